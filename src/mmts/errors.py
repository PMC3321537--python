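"""Exception hierarchy for the MMTS pipeline."""


class MMTSError(Exception):
    """Base class for all package errors."""


class ConstantFeatureError(MMTSError):
    """A feature has zero variance within the fitting class."""

    def __init__(self, feature: str, class_id: str | None = None):
        self.feature = feature
        self.class_id = class_id
        where = f" in class '{class_id}'" if class_id else ""
        super().__init__(f"feature '{feature}'{where} is constant (zero standard deviation)")


class CollinearityError(MMTSError):
    """A Gram-Schmidt component collapsed: the feature is (near-)collinear with its predecessors."""

    def __init__(self, index: int, feature: str, class_id: str | None = None):
        self.index = index
        self.feature = feature
        self.class_id = class_id
        where = f" in class '{class_id}'" if class_id else ""
        super().__init__(
            f"Gram-Schmidt component {index} ('{feature}'){where} is exactly or nearly "
            f"collinear with preceding features; the Mahalanobis space is rank deficient"
        )


class ValidationAbort(MMTSError):
    """Raised in strict mode when the measurement scale fails separability validation."""


class StageError(MMTSError):
    """Wraps a fatal error with the pipeline stage it occurred in."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
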