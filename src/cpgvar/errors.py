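"""Exception hierarchy for cpgvar.

All package-specific failures derive from :class:`CpgvarError` so callers
(and the CLI) can catch one base class.
"""


class CpgvarError(Exception):
    """Base class for all cpgvar errors."""


class InvalidBaseError(CpgvarError):
    """A nucleotide outside {A, C, G, T} where an unambiguous base is required."""


class DegenerateVariantError(CpgvarError):
    """A variant whose two alleles are identical."""


class InconsistentAncestralError(CpgvarError):
    """An ancestral allele that matches neither allele of the variant."""


class SchemaError(CpgvarError):
    """A malformed input file: missing column, bad row, out-of-range value."""


class ConfigError(CpgvarError):
    """An invalid configuration value (negative width, non-increasing edges...)."""


class UndefinedLdError(CpgvarError):
    """r-squared requested for a monomorphic locus (denominator zero)."""


class SeparationError(CpgvarError):
    """Logistic fit failed: complete/quasi-complete separation or non-convergence."""


class CollinearityError(CpgvarError):
    """A model covariate is constant, so its coefficient is not identified."""


class InfeasibleMatchingError(CpgvarError):
    """A matching stratum has fewer pool SNPs than the index set requires."""


class EmptySummaryError(CpgvarError):
    """A summary was requested for an empty collection of values."""
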