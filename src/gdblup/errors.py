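"""Exception hierarchy.

All package-specific failures derive from :class:`GdblupError` so callers
(and the CLI) can distinguish bad input (exit code 2) from numerical
non-convergence (exit code 3).
"""


class GdblupError(Exception):
    """Base class for all gdblup errors."""


class InputError(GdblupError):
    """Malformed or inconsistent user input (files, tables, dimensions)."""


class DimensionError(InputError):
    """Empty or non-conforming matrix dimensions."""


class DegenerateSNPError(InputError):
    """A SNP with allele frequency 0 or 1 reached a coding routine."""


class DegenerateIndividualError(InputError):
    """An individual with a zero diagonal in a raw relationship matrix
    (e.g. heterozygous at no SNP) cannot be correlation-normalized."""


class LinkageError(InputError):
    """Phenotyped individuals without genotypes (or vice versa)."""


class FactorizationError(GdblupError):
    """A matrix expected to be positive definite failed to factor."""


class ConvergenceError(GdblupError):
    """An iterative algorithm exhausted its iteration budget."""
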