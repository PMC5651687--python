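"""Exception types raised by the simulator."""


class EqsimError(Exception):
    """Base class for all eqsim errors."""


class UnknownUnitError(EqsimError, KeyError):
    """A stimulus identifier does not name a unit in the network."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message plain
        return self.args[0] if self.args else ""


class ContractViolationError(EqsimError, ValueError):
    """An operation was called with arguments outside its contract."""


class ConfigurationError(EqsimError, ValueError):
    """A protocol, stage or structure definition is invalid."""


class StageNonConvergenceError(EqsimError, RuntimeError):
    """A training stage failed its mastery criterion too many times.

    Expected for pathological parameter sets (e.g. a zero learning rate,
    where the network can never exceed chance responding).
    """

    def __init__(self, stage_name: str, attempts: int):
        self.stage_name = stage_name
        self.attempts = attempts
        super().__init__(
            f"stage {stage_name!r} did not reach its criterion in "
            f"{attempts} block repetitions"
        )
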