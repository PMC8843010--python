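"""Exception types shared across the simulator."""


class ConfigurationError(ValueError):
    """A parameter set violates its documented invariants."""


class SensorFaultError(ValueError):
    """A controller input was non-finite (NaN/inf angle or torque)."""


class SimulationFaultError(RuntimeError):
    """The simulated plant left its physically plausible envelope."""


class InvalidInputError(ValueError):
    """A data argument (empty sequence, negative count, ...) is unusable."""
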