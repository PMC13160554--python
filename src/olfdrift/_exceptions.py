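"""Package-level exception types."""


class OlfdriftError(Exception):
    """Base class for all package errors."""


class ConfigError(OlfdriftError, ValueError):
    """Invalid configuration, rule, or dimension mismatch."""


class ZeroVarianceError(OlfdriftError, ValueError):
    """A correlation/cosine was requested on constant or zero input."""


class SimulationDivergence(OlfdriftError, FloatingPointError):
    """Membrane state became non-finite during integration."""

    def __init__(self, cell: int, t_ms: float):
        self.cell = int(cell)
        self.t_ms = float(t_ms)
        super().__init__(f"non-finite membrane state in cell {cell} at t={t_ms:g} ms")
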