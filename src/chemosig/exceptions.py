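"""Exception hierarchy for chemosig.

All chemosig-specific errors derive from :class:`ChemosigError` so callers
can catch the whole family; most also derive from the matching builtin
(``ValueError``/``RuntimeError``) so generic handling keeps working.
"""


class ChemosigError(Exception):
    """Base class for all chemosig errors."""


class ConfigurationError(ChemosigError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class ValidationError(ChemosigError, ValueError):
    """An input table, matrix or vector violates its contract."""


class AlignmentError(ChemosigError, ValueError):
    """Expression and clinical inputs cannot be aligned on sample ids."""


class DegenerateSplitError(ChemosigError, ValueError):
    """A gene cannot be dichotomized (constant or majority-tied values)."""


class UndefinedTestError(ChemosigError, ValueError):
    """A statistical test is undefined on the given data (e.g. no events)."""


class EstimationError(ChemosigError, RuntimeError):
    """A proportion estimate could not be produced (e.g. all-zero NNLS fit)."""
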