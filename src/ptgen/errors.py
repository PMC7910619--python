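"""Exception hierarchy for ptgen."""


class PtgenError(Exception):
    """Base class for all ptgen errors."""


class LayoutError(PtgenError, ValueError):
    """Invalid node-layout specification."""


class ParameterError(PtgenError, ValueError):
    """Invalid hyperparameter or model-state value."""


class AssignmentInfeasibleError(PtgenError, ValueError):
    """One-to-one assignment requested with fewer nodes than items."""


class CoverageError(PtgenError, KeyError):
    """A composition refers to elements absent from the descriptor table."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "elements not covered by the table: " + ", ".join(self.missing)
        )


class FormulaParseError(PtgenError, ValueError):
    """Malformed chemical formula string."""


class SamplingError(PtgenError, RuntimeError):
    """An MCMC kernel failed (numerics, barrier, or retry budget)."""


class NumericalError(PtgenError, RuntimeError):
    """Linear-algebra failure that jitter escalation could not repair."""
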