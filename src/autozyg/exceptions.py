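"""Exception taxonomy shared across the pipeline."""


class AutozygError(Exception):
    """Base class for package errors."""


class ConfigError(AutozygError):
    """Invalid configuration or distribution spec."""


class StructuralError(AutozygError):
    """Structurally inconsistent inputs (mismatched sites, unsorted data...)."""


class CapacityError(AutozygError):
    """Input too small for the requested operation (e.g. founder panel)."""


class PipelineError(AutozygError):
    """A pipeline stage cannot proceed (e.g. empty site set after QC)."""


class NumericalError(AutozygError):
    """Non-finite or infeasible numerical state."""
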