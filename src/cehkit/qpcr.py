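"""Calibrated qPCR copy-number assignment for the RCCX modular locus.

The RCCX module (RP-C4-CYP21-TNX) varies in copy number; RP1 sits upstream
and is always one copy per chromosome (two per diploid genome), so the
raw relative copy number of a target gene is 2 * 2^-(dCt) against RP1.
Raw values systematically underestimate true copies, so a linear map
fitted on reference samples with known copy numbers (true = a*measured + b)
calibrates them before nearest-integer assignment. A call is internally
valid when C4A + C4B == C4L + C4S == TNXA + 2: all three quantities count
the total number of RCCX modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

RCCX_GENES = ("C4A", "C4B", "C4L", "C4S", "TNXA")
REF_GENE = "RP1"


def relative_copy(
    ct_target: Sequence[float],
    ct_rp1: Sequence[float],
    efficiency: float = 2.0,
) -> float:
    """Raw relative copies = 2 * efficiency^-(mean Ct_target - mean Ct_RP1).

    NaN replicates are the no-amplification sentinel: an all-sentinel target
    is zero copies; a sentinel reference anchor is an error.
    """
    t = np.asarray(list(ct_target), dtype=float)
    r = np.asarray(list(ct_rp1), dtype=float)
    if t.size == 0 or r.size == 0:
        raise ValueError("need at least one replicate")
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("reference gene RP1 did not amplify")
    t = t[np.isfinite(t)]
    if t.size == 0:
        return 0.0
    d_ct = t.mean() - r.mean()
    return float(2.0 * efficiency ** (-d_ct))


@dataclass
class Calibration:
    slope: float
    intercept: float
    r_value: float

    def apply(self, measured: float) -> float:
        return self.slope * measured + self.intercept


def fit_calibration(
    references: Sequence[tuple[float, float]],
) -> Calibration:
    """Least-squares fit true = a * measured + b on reference samples.

    ``references`` pairs (measured relative copies, known true copies);
    at least two distinct known values are required.
    """
    measured = np.array([m for m, _ in references], dtype=float)
    true = np.array([t for _, t in references], dtype=float)
    if len(set(true.tolist())) < 2:
        raise ValueError("need at least two distinct known copy values")
    res = stats.linregress(measured, true)
    return Calibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_value=float(res.rvalue),
    )


IDENTITY_CALIBRATION = Calibration(slope=1.0, intercept=0.0, r_value=1.0)


@dataclass
class CopyNumberCall:
    sample_id: str
    raw: dict[str, float]
    calibrated: dict[str, float]
    assigned: dict[str, int]
    valid: bool
    modules_total: Optional[int] = None
    totals: tuple[int, int, int] = (0, 0, 0)


def _round_half_up(x: float) -> int:
    return max(0, math.floor(x + 0.5))


def assign_copies(
    calibrated: dict[str, float],
    sample_id: str = "",
    raw: Optional[dict[str, float]] = None,
    validate: bool = True,
) -> CopyNumberCall:
    """Nearest-integer copy assignment with the internal-validation identity.

    Ties at .5 round up; integers are clamped at zero. With ``validate``,
    the call is valid iff C4A+C4B == C4L+C4S == TNXA+2, in which case the
    module total is that shared count.
    """
    assigned = {g: _round_half_up(v) for g, v in calibrated.items()}
    totals = (
        assigned.get("C4A", 0) + assigned.get("C4B", 0),
        assigned.get("C4L", 0) + assigned.get("C4S", 0),
        assigned.get("TNXA", 0) + 2,
    )
    valid = totals[0] == totals[1] == totals[2] if validate else True
    return CopyNumberCall(
        sample_id=sample_id,
        raw=dict(raw or {}),
        calibrated=dict(calibrated),
        assigned=assigned,
        valid=valid,
        modules_total=totals[0] if valid else None,
        totals=totals,
    )


def call_rccx(
    plate,
    calibration: Calibration = IDENTITY_CALIBRATION,
    genes: Sequence[str] = RCCX_GENES,
    ref_gene: str = REF_GENE,
) -> list[CopyNumberCall]:
    """End-to-end copy-number calls from a tidy Ct table.

    ``plate`` is a DataFrame with columns (sample, gene, replicate, ct);
    each sample must carry the reference gene. Raw relative copies are
    computed per gene, calibrated, and assigned with validation.
    """
    calls = []
    for sample, grp in plate.groupby("sample", sort=True):
        ref_ct = grp.loc[grp["gene"] == ref_gene, "ct"].to_numpy()
        if ref_ct.size == 0:
            raise ValueError(f"sample {sample}: missing reference gene {ref_gene}")
        raw = {}
        for gene in genes:
            ct = grp.loc[grp["gene"] == gene, "ct"].to_numpy()
            if ct.size == 0:
                continue
            raw[gene] = relative_copy(ct, ref_ct)
        calibrated = {
            g: (calibration.apply(v) if v > 0 else 0.0) for g, v in raw.items()
        }
        calls.append(
            assign_copies(calibrated, sample_id=str(sample), raw=raw)
        )
    return calls
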