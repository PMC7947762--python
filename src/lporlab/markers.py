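"""Marker-gene presence/absence matrices and the AAPB classification rule.

A genome is called a (putative) aerobic anoxygenic phototrophic bacterium
(AAPB) if it possesses the three dark-operative protochlorophyllide
oxidoreductase (DPOR) subunits BchB/BchL/BchN, both subunits of the
pheophytin-quinone type II reaction center (PufL and PufM), at least one
magnesium-protoporphyrin IX monomethyl ester cyclase (AcsF and/or BchE),
and lacks the Calvin-cycle markers RuBisCO (large chain) and/or PRK —
i.e. having both RuBisCO and PRK disqualifies the genome, which separates
anoxygenic phototrophs from oxygenic ones.

Marker presence is inferred from profile-HMM searches: a marker is present
iff at least one hit meets its model's trusted cutoff (a bit-score gate;
when no curated cutoff is available an E-value ceiling is used instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SearchIO

from .errors import TbloutParseError, ValidationError

__all__ = [
    "MARKERS",
    "HmmHit",
    "MarkerMatrix",
    "AapbCall",
    "parse_hmm_tblout",
    "read_cutoff_table",
    "presence_matrix",
    "call_aapb",
    "classify_genomes",
]

#: closed marker set, column order of the presence/absence matrix
MARKERS: tuple[str, ...] = (
    "LPOR", "BchB", "BchL", "BchN", "RuBisCO_large", "PRK",
    "BchE", "AcsF", "PufL", "PufM", "PsaA", "PsaB", "PsbA", "PsbD",
)

#: E-value ceiling applied when a model has no curated bit-score cutoff
DEFAULT_EVALUE_CEILING = 1e-5


@dataclass
class HmmHit:
    """One target-per-line hit from a HMMER tblout search."""

    genome_id: str
    marker: str
    score: float
    evalue: float
    target_id: str = ""
    trusted_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")

    @property
    def meets_cutoff(self) -> bool:
        if self.trusted_cutoff is not None:
            return self.score >= self.trusted_cutoff
        return self.evalue <= DEFAULT_EVALUE_CEILING


@dataclass
class MarkerMatrix:
    """Genomes x markers boolean presence with per-cell provenance.

    ``presence`` is a boolean DataFrame indexed by genome id with one column
    per marker in :data:`MARKERS`; ``provenance[(genome, marker)]`` is the
    best qualifying :class:`HmmHit`, or ``None`` when the marker is absent.
    """

    presence: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [m for m in MARKERS if m not in self.presence.columns]
        if missing:
            raise ValidationError(f"matrix lacks marker columns {missing}")
        self.presence = self.presence[list(MARKERS)].astype(bool)
        self.presence.index.name = "genome_id"

    @property
    def genomes(self) -> list[str]:
        return list(self.presence.index)

    def row(self, genome_id: str) -> dict:
        return self.presence.loc[genome_id].to_dict()

    def to_tsv(self, path) -> None:
        self.presence.astype(int).to_csv(path, sep="\t", index_label="genome_id")

    @classmethod
    def from_tsv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(bool))


def _genome_of(target_id: str) -> str:
    """Genome id convention: everything before the first '|' of the target
    sequence name (plain names map to themselves)."""
    return target_id.split("|", 1)[0]


def read_cutoff_table(path) -> dict[str, float]:
    """Read the sidecar cutoff table (TSV: model_name, trusted_cutoff_bits)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise TbloutParseError(f"{path}: expected model_name and cutoff columns")
    return {str(m): float(c) for m, c in zip(df.iloc[:, 0], df.iloc[:, 1])}


def parse_hmm_tblout(path, cutoffs: dict[str, float] | None = None,
                     model_map: dict[str, str] | None = None) -> list[HmmHit]:
    """Parse a HMMER3 tblout file into :class:`HmmHit` records.

    ``model_map`` translates HMM model names to marker names (identity for
    names already in :data:`MARKERS`); ``cutoffs`` supplies trusted bit-score
    cutoffs keyed by model name.  Hits are parsed regardless of score; cutoff
    gating happens in :func:`presence_matrix` via ``HmmHit.meets_cutoff``.
    """
    path = Path(path)
    cutoffs = cutoffs or {}
    model_map = model_map or {}
    hits: list[HmmHit] = []
    try:
        results = list(SearchIO.parse(str(path), "hmmer3-tab"))
    except Exception as exc:  # SearchIO raises bare ValueError with no location
        raise TbloutParseError(f"{path}: {exc}") from exc
    for query in results:
        marker = model_map.get(query.id, query.id)
        if marker not in MARKERS:
            raise TbloutParseError(
                f"{path}: query {query.id!r} maps to no known marker")
        for hit in query.hits:
            hits.append(HmmHit(
                genome_id=_genome_of(hit.id),
                marker=marker,
                score=float(hit.bitscore),
                evalue=float(hit.evalue),
                target_id=hit.id,
                trusted_cutoff=cutoffs.get(query.id),
            ))
    return hits


def presence_matrix(hits: list[HmmHit],
                    genomes: list[str] | None = None) -> MarkerMatrix:
    """Build the presence/absence matrix: a marker is present in a genome iff
    at least one hit meets its cutoff; provenance records the best (highest
    scoring) qualifying hit.  Order of the hit list is irrelevant."""
    if genomes is None:
        genomes = sorted({h.genome_id for h in hits})
    data = {g: {m: False for m in MARKERS} for g in genomes}
    provenance: dict[tuple[str, str], HmmHit | None] = {
        (g, m): None for g in genomes for m in MARKERS}
    for hit in sorted(hits, key=lambda h: (h.genome_id, h.marker, -h.score)):
        if hit.genome_id not in data or not hit.meets_cutoff:
            continue
        key = (hit.genome_id, hit.marker)
        if provenance[key] is None or hit.score > provenance[key].score:
            provenance[key] = hit
            data[hit.genome_id][hit.marker] = True
    df = pd.DataFrame.from_dict(data, orient="index").reindex(genomes)
    return MarkerMatrix(df, provenance)


@dataclass
class AapbCall:
    """Classification of one genome with clause-level reasons."""

    genome_id: str
    is_aapb: bool
    reasons: list[str]


def call_aapb(row: dict, genome_id: str = "",
              strict_calvin: bool = False) -> AapbCall:
    """Apply the AAPB rule to one presence/absence row.

    is_aapb = (BchB & BchL & BchN) & (PufL & PufM) & (AcsF | BchE)
              & not (RuBisCO_large & PRK)

    With ``strict_calvin`` the last clause requires both Calvin-cycle markers
    absent instead of at least one.
    """
    missing = [m for m in MARKERS if m not in row]
    if missing:
        raise ValidationError(f"incomplete marker row, missing {missing}")
    dpor = bool(row["BchB"] and row["BchL"] and row["BchN"])
    rc2 = bool(row["PufL"] and row["PufM"])
    cyclase = bool(row["AcsF"] or row["BchE"])
    if strict_calvin:
        no_calvin = not (row["RuBisCO_large"] or row["PRK"])
    else:
        no_calvin = not (row["RuBisCO_large"] and row["PRK"])
    clauses = [
        ("DPOR subunits BchB+BchL+BchN", dpor),
        ("RC type II (PufL and PufM)", rc2),
        ("cyclase (AcsF and/or BchE)", cyclase),
        ("lacks RuBisCO and/or PRK", no_calvin),
    ]
    reasons = [f"{'satisfied' if ok else 'violated'}: {name}"
               for name, ok in clauses]
    return AapbCall(genome_id=genome_id,
                    is_aapb=dpor and rc2 and cyclase and no_calvin,
                    reasons=reasons)


def classify_genomes(matrix: MarkerMatrix,
                     strict_calvin: bool = False) -> list[AapbCall]:
    """Classify every genome in a matrix."""
    return [call_aapb(matrix.row(g), g, strict_calvin=strict_calvin)
            for g in matrix.genomes]
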