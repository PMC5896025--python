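"""Exception hierarchy shared across the package."""


class SoxOctError(Exception):
    """Base class for all package errors."""


class ValidationError(SoxOctError, ValueError):
    """Invalid user input: out-of-range parameter, malformed grid, bad config key."""


class SolverError(SoxOctError, RuntimeError):
    """Equilibrium solver failed to converge or violated conservation."""


class FitError(SoxOctError, RuntimeError):
    """Nonlinear least-squares fit failed or returned an unusable optimum."""


class DegenerateDataError(FitError):
    """Data carry no signal to fit (e.g. all-zero bound fractions)."""


class FormatError(SoxOctError, ValueError):
    """Malformed input file (FASTA/CSV/JSON)."""


class ReportingError(SoxOctError, ValueError):
    """Inconsistent inputs to a report (e.g. cofactor entry without its baseline)."""
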