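"""Typed exceptions.

Every failure mode raised by the analysis names the stage it came from;
nothing downstream is allowed to propagate silent NaNs.
"""


class PhysfixError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhysfixError):
    """Invalid protocol, geometry, design or pipeline configuration."""


class TraceFormatError(PhysfixError):
    """Malformed trace or marker file; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EstimationFailureError(PhysfixError):
    """No acceptable terminal segment found for a cycle/branch."""

    def __init__(self, message: str, cycle: int | None = None, branch: str | None = None):
        self.cycle = cycle
        self.branch = branch
        tag = "".join(
            f" [{k}={v}]" for k, v in (("cycle", cycle), ("branch", branch)) if v is not None
        )
        super().__init__(message + tag)


class DegenerateFitError(PhysfixError):
    """Regression impossible: zero variance or zero slope."""


class DegenerateGeometryError(PhysfixError):
    """Marker too close to the torsion axis for an angle to be defined."""


class FittingError(PhysfixError):
    """Mixed-model estimation failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        self.diagnostics = diagnostics or {}
        super().__init__(message)
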