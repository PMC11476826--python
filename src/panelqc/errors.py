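"""Exception hierarchy for panelqc."""


class PanelQCError(Exception):
    """Base class for all panelqc errors."""


class FormatError(PanelQCError):
    """A file or table does not conform to the expected layout."""


class UnitError(PanelQCError):
    """An expression matrix is in the wrong unit for the requested operation."""


class DegenerateInputError(PanelQCError):
    """Input is numerically degenerate (constant vector, all-zero column, ...)."""
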