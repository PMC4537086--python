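"""Exception hierarchy shared across the package."""


class CoalDateError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(CoalDateError, ValueError):
    """A simulation configuration violates its invariants."""


class InvalidParameterError(CoalDateError, ValueError):
    """A scalar parameter is outside its admissible range."""


class MissingTaxonError(CoalDateError, LookupError):
    """A queried leaf label is absent from the tree."""


class UndefinedQuantityError(CoalDateError, ValueError):
    """The requested quantity is undefined for this input (e.g. basal node of a cherry)."""


class InvalidQueryError(CoalDateError, ValueError):
    """A clade query is structurally invalid (e.g. ingroup equals all leaves)."""


class NewickParseError(CoalDateError, ValueError):
    """Malformed or unsupported Newick input."""


class UnsupportedFlagError(CoalDateError, ValueError):
    """An ms command-line flag outside the supported subset."""


class MsCommandError(CoalDateError, ValueError):
    """A structurally inconsistent ms command (e.g. -I sum disagreeing with nsam)."""


class AlignmentError(CoalDateError, ValueError):
    """Malformed alignment input (ragged records, empty alignment)."""


class IntervalError(CoalDateError, ValueError):
    """A recombination interval is out of bounds or malformed."""
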