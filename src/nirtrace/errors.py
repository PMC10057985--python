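"""Exception hierarchy for the pipeline.

Every error a caller is expected to branch on derives from
:class:`NirtraceError`; parameter misuse additionally derives from
``ValueError`` so generic callers behave sensibly.
"""


class NirtraceError(Exception):
    """Base class for package errors."""


class ParameterError(NirtraceError, ValueError):
    """Invalid parameter value (window sizes, component counts, fractions...)."""


class ParseError(NirtraceError, ValueError):
    """Malformed spectral table; the message names the offending row/column."""


class GridError(NirtraceError, ValueError):
    """Wavenumber grid invalid or mismatched between model and data."""


class DegenerateSpectrumError(NirtraceError, ValueError):
    """A spectrum violates an operator precondition (zero variance, all-zero...)."""


class DegenerateFitError(NirtraceError, ValueError):
    """A per-spectrum regression produced an unusable fit (|slope| ~ 0)."""


class ConvergenceError(NirtraceError, RuntimeError):
    """Iterative fit failed to converge within its iteration budget."""


class StratificationError(NirtraceError, ValueError):
    """A class is too small to stratify the requested split."""


class LabelError(NirtraceError, ValueError):
    """A label outside the fitted two-class set was encountered."""


class PipelineStepError(NirtraceError, RuntimeError):
    """Wraps an error raised inside a preprocessing pipeline step.

    Carries the zero-based step index and kind so grid drivers can report
    which stage of a combination failed.
    """

    def __init__(self, step_index: int, kind: str, original: Exception):
        self.step_index = step_index
        self.kind = kind
        self.original = original
        super().__init__(f"step {step_index} ({kind}): {original}")
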