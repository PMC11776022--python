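"""Package-wide exception types."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


class NoVillousTissueError(RuntimeError):
    """Raised when a computation's scope contains no villous pixels."""

    def __init__(self, message: str = "no villous tissue"):
        super().__init__(message)


class SubjectExclusionError(RuntimeError):
    """Raised when a subject fails a validity rule and must be excluded.

    Carries the subject id and the reason so pipelines can log the exclusion
    instead of aborting.
    """

    def __init__(self, subject_id, reason: str):
        self.subject_id = subject_id
        self.reason = reason
        super().__init__(f"subject {subject_id} excluded: {reason}")
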