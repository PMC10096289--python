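"""Exception hierarchy shared across the pipeline.

Every error raised by this package derives from :class:`MoaDtiError`, so
callers (and the command-line layer) can distinguish pipeline failures from
programming errors with a single ``except``.
"""


class MoaDtiError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(MoaDtiError, ValueError):
    """Inputs violate an operation's preconditions."""


class EmptyInputError(InvalidInputError):
    """An operation that needs at least one element received none."""


class InvalidConfigError(MoaDtiError, ValueError):
    """A configuration value is outside its declared domain."""


class ParseError(MoaDtiError, ValueError):
    """A file or table could not be parsed; carries location context."""


class StructureParseError(ParseError):
    """A SMILES string could not be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class LookupMissError(MoaDtiError, KeyError):
    """A requested gene/compound is absent from the queried container."""


class CapacityError(MoaDtiError, ValueError):
    """A sampling request exceeds the available universe."""


class DegenerateLabelError(InvalidInputError):
    """Supervised fit received a single-class label vector."""


class UndefinedMetricError(InvalidInputError):
    """A ranking metric is undefined (e.g. single-class labels)."""


class ShapeError(MoaDtiError, ValueError):
    """Array dimensions do not match the fitted/declared contract."""
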