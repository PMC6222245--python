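"""Exception hierarchy for seegplan."""


class SeegPlanError(Exception):
    """Base class for all seegplan errors."""


class TableParseError(SeegPlanError):
    """A trajectory table (CSV) could not be parsed or violates an invariant."""


class AffineFormatError(SeegPlanError):
    """An affine file has the wrong shape or is singular."""


class BundleValidationError(SeegPlanError):
    """A persisted model bundle violates its schema or invariants."""


class SpaceMismatchError(SeegPlanError):
    """An operation received objects tagged with incompatible coordinate spaces."""


class ContractError(SeegPlanError):
    """A precondition of an operation was violated."""


class GenerationError(SeegPlanError):
    """The synthetic generator produced geometry that fails its own checks."""
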