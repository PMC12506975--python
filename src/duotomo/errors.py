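"""Exception hierarchy for duotomo."""


class DuotomoError(Exception):
    """Base class for all duotomo errors."""


class InvalidGeometryError(DuotomoError):
    pass


class RoleAssignmentError(DuotomoError):
    pass


class InvalidGridError(DuotomoError):
    pass


class GenerationError(DuotomoError):
    pass


class InvalidProfileError(DuotomoError):
    pass


class TruncationError(DuotomoError):
    """Recording window too short for the maximum time of flight."""


class IncompleteCompoundError(DuotomoError):
    """Synthetic-aperture compound is missing per-emitter frames."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"missing frames for emitters {self.missing}")


class SurfaceNotFoundError(DuotomoError):
    pass


class UndefinedCNRError(DuotomoError):
    pass


class ZoneConstructionError(DuotomoError):
    pass


class UndefinedFeatureError(DuotomoError):
    pass


class StandardizationError(DuotomoError):
    pass


class ModelError(DuotomoError):
    pass


class StageError(DuotomoError):
    """Pipeline stage failure carrying the stage name and case id."""

    def __init__(self, stage, case_id, cause):
        self.stage = stage
        self.case_id = case_id
        super().__init__(f"stage '{stage}' failed for case '{case_id}': {cause}")
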