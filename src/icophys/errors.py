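"""Exception types shared across the package."""


class ParameterError(ValueError):
    """Invalid parameter value passed to a generator or analysis routine."""


class ScheduleFormatError(ValueError):
    """A schedule/recording file violates the on-disk format or an invariant.

    Carries enough context (line number, field) to locate the offending row.
    """

    def __init__(self, message: str, line: int | None = None, field: str | None = None):
        parts = [message]
        if line is not None:
            parts.append(f"line {line}")
        if field is not None:
            parts.append(f"field '{field}'")
        super().__init__(" — ".join(parts))
        self.line = line
        self.field = field


class AnalysisError(RuntimeError):
    """An analysis step cannot proceed (e.g. no qualifying trials/spikes)."""
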