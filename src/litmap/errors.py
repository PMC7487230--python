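"""Exception hierarchy shared across the pipeline."""


class LitmapError(Exception):
    """Base class for all litmap errors."""


class CorpusFormatError(LitmapError):
    """A bibliographic input file violates its dialect contract."""


class SchemeValidationError(LitmapError):
    """A concept scheme or keyword map fails validation.

    Carries the full list of violations so a curator can fix them in one pass.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "concept scheme validation failed with %d violation(s):\n  %s"
            % (len(self.violations), "\n  ".join(self.violations))
        )


class ConfigError(LitmapError):
    """A synthetic-data configuration is invalid or infeasible."""
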