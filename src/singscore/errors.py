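"""Exception hierarchy shared across the package."""


class SingscoreError(Exception):
    """Base class for all package-specific errors."""


class InputError(SingscoreError, ValueError):
    """An argument or audio input violates a precondition."""


class FormatError(SingscoreError, ValueError):
    """A file could not be parsed in the expected format."""


class AnnotationMismatchError(SingscoreError, ValueError):
    """Syllable labels cannot be matched as an in-order subsequence of the template."""


class SilentRecordingError(SingscoreError, ValueError):
    """No usable voiced content was found in a recording."""


class ScoringError(SingscoreError, ValueError):
    """A scoring stage received degenerate data; carries stage provenance."""

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message if stage is None else f"[{stage}] {message}")
        self.stage = stage
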