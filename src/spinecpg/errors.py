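"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A simulation or analysis parameter is outside its valid range."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the requested statistic
    (e.g. zero-mean ΔF for relative intensity, coincident midline points)."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined for this input (e.g. alternation index
    with fewer than two events)."""
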