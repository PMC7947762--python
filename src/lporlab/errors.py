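"""Exception types shared across the toolkit."""


class LporlabError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(LporlabError, ValueError):
    """Input violates a structural invariant (grids, lengths, signs, units)."""


class SpectralParseError(LporlabError, ValueError):
    """A tabular spectral / trace file could not be parsed."""


class TbloutParseError(LporlabError, ValueError):
    """A HMMER tblout line could not be parsed."""


class IdentifiabilityError(LporlabError, RuntimeError):
    """The data carry no information about the requested parameter
    (e.g. a titration that is entirely bound or entirely free)."""


class NoTransitionError(LporlabError, RuntimeError):
    """A melting-curve trace shows no detectable unfolding transition."""
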