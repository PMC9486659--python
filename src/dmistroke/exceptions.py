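"""Exception types raised by the pipeline."""


class FormatError(ValueError):
    """Malformed or inconsistent input files (image/gradient-table mismatch)."""


class SchemeError(ValueError):
    """Acquisition scheme lacks a component an operation requires (b=0, a shell)."""


class ConditioningError(ValueError):
    """A linear fit is underdetermined or numerically rank-deficient."""


class ConfigError(ValueError):
    """Invalid prior/phantom configuration (empty admissible region, bad range)."""
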