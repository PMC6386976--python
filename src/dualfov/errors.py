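"""Exception hierarchy for the dualfov pipeline."""


class DualFovError(Exception):
    """Base class for all dualfov errors."""


class ValidationError(DualFovError, ValueError):
    """A parameter or input violates a documented precondition."""


class PairingError(DualFovError):
    """Target and dark frames cannot be paired (channel/grid/time mismatch)."""


class SequenceIncompleteError(DualFovError):
    """A measurement sequence is missing one of its four frames."""


class DegenerateSequenceError(DualFovError):
    """Every band of a sequence failed the irradiance floor."""


class DegenerateInputError(DualFovError):
    """An input is degenerate (e.g. all-zero irradiance)."""


class EmptyPlotError(DualFovError):
    """No QC-passing spectra remain for a plot."""


class GroupingError(DualFovError):
    """A dataset grouping request is invalid (unknown factor, empty group)."""
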