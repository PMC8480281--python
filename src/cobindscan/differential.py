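"""Between-condition response groups at co-bound enhancers and strong peaks.

Co-bound enhancer sites are classified into four groups by the direction of
the (normalized) knockdown/control fold change of two factors — with the
RUNX1/CEBPA reading: group 1 = RUNX1 down & CEBPA up, group 2 = down/down,
group 3 = up/up, group 4 = up/down. "Down" means fold change < 1; a fold
change of exactly 1 counts as up (inclusive boundary, configurable via
`boundary`).

Strong peaks from the two conditions are partitioned into redistribution
groups by cross-condition summit matching (same 200 bp one-to-one rule as
co-localization): group A = strong in control only, B = shared, C = strong
after knockdown only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colocalization import match_summits
from .signal_quant import percent_change, summarize_group, welch_t


class EnhancerGroup(str, enum.Enum):
    group1 = "group1"  # factor A down, factor B up
    group2 = "group2"  # down / down
    group3 = "group3"  # up / up
    group4 = "group4"  # up / down


class RedistributionGroup(str, enum.Enum):
    A = "A"  # control only
    B = "B"  # shared
    C = "C"  # knockdown only


def classify_enhancer_groups(fc_a, fc_b, boundary: float = 1.0):
    """Group sites by fold-change direction of two factors (A=RUNX1-like, B=CEBPA-like)."""
    fa = np.asarray(fc_a, dtype=float)
    fb = np.asarray(fc_b, dtype=float)
    if np.any(fa <= 0) or np.any(fb <= 0):
        raise ValueError("fold changes must be positive")
    a_up = fa >= boundary
    b_up = fb >= boundary
    table = np.array(
        [[EnhancerGroup.group2, EnhancerGroup.group1],
         [EnhancerGroup.group4, EnhancerGroup.group3]],
        dtype=object,
    )
    # scalar inputs index to the bare group, arrays to an object array
    return table[a_up.astype(int), b_up.astype(int)]


@dataclass
class RedistributionResult:
    group_a: list  # control-only strong peaks
    group_b: list  # (control peak, kd peak) matched pairs
    group_c: list  # knockdown-only strong peaks


def classify_redistribution(strong_ctrl, strong_kd, max_dist: int = 200) -> RedistributionResult:
    """Partition strong peaks of two conditions into A (control-only), B (shared), C (KD-only)."""
    pairs = match_summits(strong_ctrl, strong_kd, max_dist=max_dist)
    matched_ctrl = {s.peak_a for s in pairs}
    matched_kd = {s.peak_b for s in pairs}
    return RedistributionResult(
        group_a=[p for p in strong_ctrl if p not in matched_ctrl],
        group_b=[(s.peak_a, s.peak_b) for s in pairs],
        group_c=[p for p in strong_kd if p not in matched_kd],
    )


def group_response_table(groups, signal: pd.DataFrame, column_pairs) -> pd.DataFrame:
    """Per group x factor: control/KD mean +- SEM, percent change and Welch p.

    `groups` is a per-row group label array aligned with `signal`;
    `column_pairs` maps a factor name to its (control column, kd column).
    Groups with fewer than two sites are flagged and excluded from testing.
    """
    groups = np.asarray([getattr(g, "value", g) for g in groups])
    rows = []
    for label in pd.unique(groups):
        mask = groups == label
        for factor, (ctrl_col, kd_col) in column_pairs.items():
            ctrl = signal.loc[mask, ctrl_col].to_numpy(dtype=float)
            kd = signal.loc[mask, kd_col].to_numpy(dtype=float)
            if mask.sum() < 2:
                rows.append(dict(group=label, factor=factor, n=int(mask.sum()),
                                 mean_control=float(ctrl.mean()) if ctrl.size else np.nan,
                                 sem_control=np.nan, mean_kd=float(kd.mean()) if kd.size else np.nan,
                                 sem_kd=np.nan, percent_change=np.nan, welch_p=np.nan,
                                 flagged=True))
                continue
            sc = summarize_group(ctrl, label)
            sk = summarize_group(kd, label)
            _, p = welch_t(ctrl, kd)
            rows.append(dict(group=label, factor=factor, n=sc.n,
                             mean_control=sc.mean, sem_control=sc.sem,
                             mean_kd=sk.mean, sem_kd=sk.sem,
                             percent_change=percent_change(sc.mean, sk.mean) if sc.mean > 0 else np.nan,
                             welch_p=p, flagged=False))
    return pd.DataFrame(rows)
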