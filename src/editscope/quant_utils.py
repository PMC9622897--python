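"""Small self-contained expression quantifications.

FPKM from per-gene fragment counts, relative qPCR expression by the
2^-ddCt method, absolute copy number from a qPCR standard curve, and
dual-luciferase editing-reporter normalization. All operations are pure
and deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit of Ct against log10(copies); slope < 0 for a valid assay
    (each 10-fold dilution raises Ct by |slope| cycles, ~3.32 at 100%
    efficiency)."""

    slope: float
    intercept: float
    r_squared: float

    def quantify(self, ct: float) -> float:
        """Invert the curve: copies = 10^((Ct - intercept) / slope)."""
        return float(10 ** ((ct - self.intercept) / self.slope))


def fpkm(
    fragment_counts: Dict[str, int], lengths: Dict[str, int]
) -> Dict[str, float]:
    """Fragments Per Kilobase of exon model per Million mapped fragments.

    FPKM_g = counts_g * 1e9 / (length_g * total_counts). Lengths are in
    bases; the total is the sum over the supplied genes.
    """
    total = sum(fragment_counts.values())
    if total <= 0:
        raise ValueError("total fragment count must be positive")
    out = {}
    for gene, count in fragment_counts.items():
        length = lengths[gene]
        if length <= 0:
            raise ValueError(f"gene {gene}: length must be positive")
        out[gene] = count * 1e9 / (length * total)
    return out


def ddct(
    ct_target_test: float | Sequence[float],
    ct_ref_test: float | Sequence[float],
    ct_target_cal: float | Sequence[float],
    ct_ref_cal: float | Sequence[float],
) -> float:
    """Relative expression by 2^-ddCt.

    Each arm may be a single Ct or replicate Cts, which are averaged
    before differencing:
    ddCt = (Ct_target - Ct_ref)_test - (Ct_target - Ct_ref)_calibrator.
    """
    arms = []
    for name, val in (
        ("target/test", ct_target_test),
        ("reference/test", ct_ref_test),
        ("target/calibrator", ct_target_cal),
        ("reference/calibrator", ct_ref_cal),
    ):
        arr = np.atleast_1d(np.asarray(val, dtype=float))
        if arr.size == 0 or np.any(np.isnan(arr)):
            raise ValueError(f"missing Ct values for {name}")
        if np.any(arr <= 0):
            raise ValueError(f"Ct values for {name} must be positive")
        arms.append(float(arr.mean()))
    delta_test = arms[0] - arms[1]
    delta_cal = arms[2] - arms[3]
    return float(2.0 ** -(delta_test - delta_cal))


def fit_standard_curve(
    copies: Sequence[float], cts: Sequence[float]
) -> StandardCurve:
    """Least-squares Ct vs log10(copies) from a dilution series.

    Requires >= 3 points spanning >= 2 logs and a negative slope
    (amplification must reduce Ct as template increases).
    """
    copies = np.asarray(copies, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if copies.size < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    logc = np.log10(copies)
    if logc.max() - logc.min() < 2:
        raise ValueError("dilution series must span at least 2 logs")
    fit = stats.linregress(logc, cts)
    if fit.slope >= 0:
        raise ValueError("non-negative slope: invalid amplification")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def reporter_editing_signal(
    wells: Dict[str, Sequence[Tuple[float, float]]],
    control: str,
) -> Dict[str, Dict[str, float]]:
    """Dual-luciferase editing-reporter readout.

    wells maps condition -> list of (renilla, firefly) per well; the
    renilla reporter is translated only when editing converts its premature
    stop codon, firefly is the transfection control. Per-well ratio is
    renilla/firefly; wells with firefly <= 0 are excluded with a warning.
    Returns per condition the mean ratio, SEM, and fold change vs control.
    """
    if control not in wells:
        raise ValueError(f"control condition {control!r} not among wells")
    ratios: Dict[str, np.ndarray] = {}
    for condition, measurements in wells.items():
        vals = []
        for renilla, firefly in measurements:
            if renilla < 0:
                raise ValueError(f"{condition}: negative renilla signal")
            if firefly <= 0:
                warnings.warn(
                    f"{condition}: well with firefly <= 0 excluded", stacklevel=2
                )
                continue
            vals.append(renilla / firefly)
        if not vals:
            raise ValueError(f"{condition}: no valid wells")
        ratios[condition] = np.asarray(vals)
    control_mean = ratios[control].mean()
    out = {}
    for condition, vals in ratios.items():
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[condition] = {
            "mean_ratio": float(vals.mean()),
            "sem": sem,
            "fold_vs_control": float(vals.mean() / control_mean),
            "n_wells": int(vals.size),
        }
    return out
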