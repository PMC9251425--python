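"""Exception hierarchy for the plantdiet package."""


class PlantDietError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PlantDietError):
    """An invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class ClassificationError(PlantDietError):
    """A food item code with no food-group mapping; carries the code."""

    def __init__(self, code):
        self.code = code
        super().__init__(f"unmapped food item code: {code!r}")


class MapValidationError(PlantDietError):
    """A food-group map violating its structural requirements."""


class MissingDataError(PlantDietError):
    """Required records are absent (e.g. no recall days, no baseline year)."""


class SampleSizeError(PlantDietError):
    """Too few observations for the requested operation."""


class AlignmentError(PlantDietError):
    """Tables that must share participant ids (or lengths) do not."""


class ChronologyError(PlantDietError):
    """Event/censor years inconsistent with the baseline year."""


class SchemaError(PlantDietError):
    """A table missing required columns; lists the offending columns."""

    def __init__(self, table: str, missing):
        self.table = table
        self.missing = list(missing)
        super().__init__(
            f"table {table!r} is missing required columns: {', '.join(self.missing)}"
        )


class ConvergenceError(PlantDietError):
    """Model fitting failed to converge; carries diagnostics in the message."""
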