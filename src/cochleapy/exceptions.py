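"""Exception hierarchy for cochleapy."""


class CochleapyError(Exception):
    """Base class for all cochleapy errors."""


class ParameterError(CochleapyError, ValueError):
    """A generative or configuration parameter is outside its valid domain."""


class DegenerateGeometryError(CochleapyError, ValueError):
    """Landmark configuration does not determine the requested geometry
    (e.g. collinear points cannot define a plane)."""


class InsufficientLandmarksError(CochleapyError, ValueError):
    """Too few landmarks of a required structure to perform a measurement."""


class ContactCountError(CochleapyError, ValueError):
    """An electrode measurement received a contact count other than the
    expected 12."""

    def __init__(self, observed: int, subject_id: str | None = None):
        self.observed = observed
        self.subject_id = subject_id
        where = f" for subject {subject_id!r}" if subject_id else ""
        super().__init__(
            f"expected 12 electrode contacts{where}, observed {observed}"
        )


class InsertionError(CochleapyError, ValueError):
    """The insertion trajectory is too short for the requested electrode
    placement."""

    def __init__(self, requested_depth: float, max_feasible_depth: float):
        self.requested_depth = requested_depth
        self.max_feasible_depth = max_feasible_depth
        super().__init__(
            f"insertion trajectory too short: deepest contact would sit at "
            f"arc length {requested_depth:.3f} mm but the trajectory ends at "
            f"{max_feasible_depth:.3f} mm"
        )


class StageError(CochleapyError, RuntimeError):
    """A pipeline stage failed; carries the stage name and subject id."""

    def __init__(self, stage: str, subject_id: str, cause: Exception):
        self.stage = stage
        self.subject_id = subject_id
        super().__init__(f"{stage} failed for subject {subject_id!r}: {cause}")


class UndefinedStatisticError(CochleapyError, ValueError):
    """A reliability statistic is undefined for the given data
    (e.g. zero total variance)."""
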