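"""Relative quantification of S vs G2 DNA by the ddCt method.

Targeted MFA validation: qPCR amplicons are measured in quadruplicate in
S-phase and G2 DNA, normalized to a calibrator amplicon (a region with no
evidence of replication in either sample), and the S-phase quantity at
each locus is reported relative to G2 = 1 as 2^(-ddCt).  Amplification
efficiency is fixed at 2 (pure ddCt, no efficiency correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CT_COLUMNS = ["amplicon", "sample", "ct"]
SAMPLES = ("S", "G2")


@dataclass
class RelativeQuantity:
    """S-phase DNA quantity relative to G2 = 1, with a replicate-SD interval."""

    amplicon: str
    quantity: float
    lo: float
    hi: float
    degenerate: bool = False


def _sample_stats(ct: pd.DataFrame, amplicon: str, sample: str) -> tuple[float, float, int]:
    rows = ct[(ct["amplicon"] == amplicon) & (ct["sample"] == sample)]["ct"]
    if len(rows) < 2:
        raise ValueError(f"need >=2 Ct replicates for ({amplicon}, {sample})")
    if (rows <= 0).any():
        raise ValueError("Ct values must be positive")
    return float(rows.mean()), float(rows.std(ddof=1)), len(rows)


def ddct_quantity(ct: pd.DataFrame, target: str, calibrator: str) -> RelativeQuantity:
    """ddCt relative quantity of ``target`` against ``calibrator``.

    dCt(sample) = mean Ct(target, sample) - mean Ct(calibrator, sample);
    ddCt = dCt(S) - dCt(G2); quantity = 2^(-ddCt).  Replicate SDs are
    propagated through the four means (standard errors in quadrature) to a
    quantity interval.  A global Ct shift (efficiency drift across plates)
    cancels exactly.
    """
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if target == calibrator:
        return RelativeQuantity(target, 1.0, 1.0, 1.0, degenerate=True)
    stats = {
        (amp, s): _sample_stats(ct, amp, s)
        for amp in (target, calibrator)
        for s in SAMPLES
    }
    d_s = stats[(target, "S")][0] - stats[(calibrator, "S")][0]
    d_g2 = stats[(target, "G2")][0] - stats[(calibrator, "G2")][0]
    ddct = d_s - d_g2
    se = np.sqrt(sum(sd**2 / n for _, sd, n in stats.values()))
    return RelativeQuantity(
        amplicon=target,
        quantity=float(2.0 ** (-ddct)),
        lo=float(2.0 ** (-(ddct + se))),
        hi=float(2.0 ** (-(ddct - se))),
    )


def quantify_all(ct: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """ddCt quantities for every non-calibrator amplicon in a Ct table."""
    rows = []
    for amp in ct["amplicon"].unique():
        if amp == calibrator:
            continue
        q = ddct_quantity(ct, amp, calibrator)
        rows.append({"amplicon": amp, "quantity": q.quantity, "lo": q.lo, "hi": q.hi})
    return pd.DataFrame(rows, columns=["amplicon", "quantity", "lo", "hi"])
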