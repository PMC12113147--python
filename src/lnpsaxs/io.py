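"""Reading/writing 1D reduced SAXS curves and multi-frame exposure QC.

The file dialect is the plain-text 3-column ``.dat`` produced by common
reduction suites: optional ``# key: value`` header comments, then
whitespace- or comma-delimited columns q, I and (optionally) the per-point
uncertainty.  q is in nm^-1 by default; an Å^-1 hint converts by ×10.

Multi-frame handling mirrors standard synchrotron practice: consecutive
short exposures of one sample are compared pairwise (here by Pearson
correlation of log10 intensity, supplemented by a median-scale check),
deviant frames — radiation damage, bubbles — are excluded, and the rest are
averaged pointwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import ScatteringCurve

__all__ = [
    "FrameSet",
    "read_curve",
    "write_curve",
    "similarity_matrix",
    "average_frames",
]

logger = logging.getLogger(__name__)

_UNIT_FACTORS = {"nm^-1": 1.0, "nm": 1.0, "angstrom": 10.0, "A^-1": 10.0}


@dataclass
class FrameSet:
    """Repeated exposures of one sample on a shared q grid, plus their
    pairwise similarity matrix (Pearson r of log10 intensity, in [-1, 1],
    symmetric, unit diagonal)."""

    frames: list[ScatteringCurve]
    similarity: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValueError("a frame set needs at least 2 frames")
        q0 = self.frames[0].q
        for f in self.frames[1:]:
            if f.q.shape != q0.shape or not np.allclose(f.q, q0, rtol=0, atol=0):
                raise ValueError("all frames must share one q grid exactly")


def read_curve(path, unit_hint: str = "nm^-1") -> ScatteringCurve:
    """Parse a 2- or 3-column text curve.

    Comment lines ('#' or non-numeric) are skipped; '# key: value' comments
    are collected into metadata.  Rows with q <= 0 or non-finite intensity
    are dropped (count logged).  Raises ValueError on files with fewer than
    2 valid rows or fewer than 2 columns.
    """
    if unit_hint not in _UNIT_FACTORS:
        raise ValueError(f"unknown unit hint {unit_hint!r}")
    factor = _UNIT_FACTORS[unit_hint]
    metadata: dict = {}
    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                continue  # non-numeric header line
            if len(values) < 2:
                raise ValueError(f"{path}: need at least 2 columns, got {len(values)}")
            if ncols is None:
                ncols = min(len(values), 3)
            rows.append(values[:ncols])
    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    data = np.asarray(rows, dtype=float)
    q = data[:, 0] * factor
    inten = data[:, 1]
    err = data[:, 2] * 1.0 if data.shape[1] > 2 else None
    keep = (q > 0) & np.isfinite(inten) & (inten >= 0)
    if err is not None:
        keep &= np.isfinite(err) & (err > 0)
    dropped = int(np.sum(~keep))
    if dropped:
        logger.info("%s: dropped %d invalid rows", path, dropped)
    q, inten = q[keep], inten[keep]
    if err is not None:
        err = err[keep]
    if q.size < 2:
        raise ValueError(f"{path}: fewer than 2 valid data rows")
    order = np.argsort(q)
    q, inten = q[order], inten[order]
    if err is not None:
        err = err[order]
    return ScatteringCurve(q=q, intensity=inten, uncertainty=err, metadata=metadata)


def write_curve(curve: ScatteringCurve, path) -> None:
    """Write a curve as '# key: value' header plus q/I/[err] columns with 9
    significant digits (deterministic formatting)."""
    with open(path, "w") as fh:
        for key, value in curve.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: q_nm^-1 intensity" +
                 (" uncertainty\n" if curve.uncertainty is not None else "\n"))
        for i in range(len(curve)):
            cols = [f"{curve.q[i]:.9g}", f"{curve.intensity[i]:.9g}"]
            if curve.uncertainty is not None:
                cols.append(f"{curve.uncertainty[i]:.9g}")
            fh.write("  ".join(cols) + "\n")


def similarity_matrix(frames: Sequence[ScatteringCurve]) -> FrameSet:
    """Pairwise Pearson correlation of log10 intensity across frames.

    Intensities are floored at the smallest positive intensity across all
    frames times 1e-3 before taking logs; frames with no positive intensity
    are rejected.  Grids must match exactly (no interpolation).
    """
    fs = FrameSet(frames=list(frames))
    positive = [f.intensity[f.intensity > 0] for f in fs.frames]
    if any(p.size == 0 for p in positive):
        raise ValueError("a frame has no positive intensities")
    floor = min(p.min() for p in positive) * 1e-3
    logs = np.stack(
        [np.log10(np.maximum(f.intensity, floor)) for f in fs.frames]
    )
    sim = np.corrcoef(logs)
    sim = np.clip(sim, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    fs.similarity = sim
    return fs


def average_frames(
    frameset: FrameSet,
    threshold: float = 0.99,
    scale_band: tuple[float, float] = (0.5, 2.0),
) -> ScatteringCurve:
    """Exclude deviant frames, average the rest pointwise.

    A frame is excluded when its mean off-diagonal similarity falls below
    ``threshold`` or when its median intensity deviates from the ensemble
    median by more than the ``scale_band`` factor range (log-correlation is
    blind to pure rescaling, so the scale check catches e.g. beam dropouts).
    The averaged uncertainty is the per-point standard error of the mean
    across kept frames, or propagated reported errors when every kept frame
    carries them and only one frame remains.
    """
    if frameset.similarity is None:
        frameset = similarity_matrix(frameset.frames)
    sim = frameset.similarity
    n = len(frameset.frames)
    mean_off = (sim.sum(axis=1) - 1.0) / (n - 1)

    medians = np.array([np.median(f.intensity) for f in frameset.frames])
    ensemble_median = np.median(medians)
    ratio = medians / ensemble_median
    scale_ok = (ratio >= scale_band[0]) & (ratio <= scale_band[1])

    keep = (mean_off >= threshold) & scale_ok
    excluded = np.flatnonzero(~keep)
    if excluded.size:
        logger.info("excluding frames %s (similarity/scale check)", excluded.tolist())
    if not np.any(keep):
        raise ValueError("all frames excluded by the similarity/scale checks")

    kept = [frameset.frames[i] for i in np.flatnonzero(keep)]
    stack = np.stack([f.intensity for f in kept])
    if np.all(stack == stack[0]):
        mean = stack[0].copy()  # bit-exact conservation for uniform frames
    else:
        mean = stack.mean(axis=0)
    if len(kept) > 1:
        err = stack.std(axis=0, ddof=1) / np.sqrt(len(kept))
        err = np.maximum(err, 1e-300)
    elif kept[0].uncertainty is not None:
        err = kept[0].uncertainty
    else:
        err = None
    metadata = dict(kept[0].metadata)
    metadata["n_frames_averaged"] = len(kept)
    metadata["n_frames_excluded"] = int(excluded.size)
    return ScatteringCurve(
        q=kept[0].q.copy(), intensity=mean, uncertainty=err, metadata=metadata
    )
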