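"""Cycle segmentation and machine-side gross angular displacement.

Cycles are located from the protocol metadata (frequency, sample rate), not
by peak detection: the loading is machine-driven, so cycle ``k`` occupies
``t`` in ``[(k-1)/f, k/f)`` exactly.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .types import CycleWindow, TorsionTrace

DEFAULT_ANALYSIS_CYCLES = (60, 120, 180)


def segment_cycles(trace: TorsionTrace) -> list[CycleWindow]:
    """Tile the trace into per-cycle half-open windows of equal length."""
    spc = trace.protocol.samples_per_cycle
    n_cycles = len(trace) // spc
    if n_cycles < 1:
        raise ConfigurationError(
            f"trace of {len(trace)} samples is shorter than one cycle ({spc} samples)"
        )
    return [CycleWindow(k + 1, k * spc, (k + 1) * spc) for k in range(n_cycles)]


def cycle_window(trace: TorsionTrace, cycle_index: int) -> CycleWindow:
    """Window of the 1-based ``cycle_index``-th cycle."""
    spc = trace.protocol.samples_per_cycle
    start = (cycle_index - 1) * spc
    if cycle_index < 1 or start + spc > len(trace):
        raise ConfigurationError(f"cycle {cycle_index} is not contained in the trace")
    return CycleWindow(cycle_index, start, start + spc)


def gross_cycle_displacement(trace: TorsionTrace, window: CycleWindow) -> float:
    """Full-cycle rotational displacement, degrees: max minus min angle.

    For a sign-symmetric cycle this equals |max| + |min|, the sum of the
    rotational extremes.  Invariant to constant angle offsets; always >= 0.
    """
    if window.start < 0 or window.end > len(trace):
        raise ConfigurationError("window lies outside the trace")
    if len(window) < 2:
        raise ConfigurationError("window must contain at least 2 samples")
    seg = trace.angle[window.start : window.end]
    return float(np.max(seg) - np.min(seg))


def decimate_trace(trace: TorsionTrace, factor: int) -> TorsionTrace:
    """Subsample every ``factor``-th sample, keeping whole cycles aligned."""
    if factor < 1 or int(factor) != factor:
        raise ConfigurationError("decimation factor must be a positive integer")
    if factor == 1:
        return trace
    spc = trace.protocol.samples_per_cycle
    if spc % factor != 0:
        raise ConfigurationError(
            f"decimation factor {factor} does not divide samples per cycle ({spc})"
        )
    from dataclasses import replace

    protocol = replace(trace.protocol, sample_rate=trace.protocol.sample_rate / factor)
    return TorsionTrace(
        time=trace.time[::factor],
        torque=trace.torque[::factor],
        angle=trace.angle[::factor],
        protocol=protocol,
    )
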