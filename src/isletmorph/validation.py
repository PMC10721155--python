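"""Program-accuracy validation against an independent reference.

Mirrors the accuracy check used for semi-automated morphometry software:
a random sample of islets of varying sizes is re-measured by an independent
reference (generator ground truth, or manual tracings supplied as CSV) and
the two measurement sets are compared metric by metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ValidationReport",
    "sample_validation_islets",
    "compare_to_reference",
    "match_to_ground_truth",
]

METRICS = ("area_um2", "beta_area_um2", "alpha_area_um2", "circularity", "feret_um")


@dataclass
class ValidationReport:
    """Per-metric agreement between pipeline and reference measurements.

    ``table`` has one row per metric: n, mean relative deviation (%), bias
    (pipeline minus reference mean), paired-t p value, pass flag.  A metric
    passes when the paired difference is statistically indistinguishable
    (p >= ``alpha``) and the mean relative deviation stays within
    ``max_relative_deviation_pct``.
    """

    table: pd.DataFrame
    alpha: float
    max_relative_deviation_pct: float

    @property
    def passed(self) -> bool:
        return bool(self.table["pass"].all())

    def summary(self) -> str:
        lines = [
            f"validation: {'PASS' if self.passed else 'FAIL'} "
            f"(paired-t alpha={self.alpha}, max mean rel dev "
            f"{self.max_relative_deviation_pct}%)"
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['metric']:<16} n={row['n']:<4.0f} "
                f"rel dev {row['mean_rel_dev_pct']:6.2f}%  bias {row['bias']:+.4g}  "
                f"p={row['p']:.4f}  {'ok' if row['pass'] else 'FAIL'}"
            )
        return "\n".join(lines)


def sample_validation_islets(
    records: pd.DataFrame, n: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Stratified random sample of ``n`` islets across area terciles.

    Sampling across terciles guarantees islets "of varying sizes"; the
    split is as even as ``n`` allows (remainder to the smaller strata).
    Deterministic for a fixed seed; fewer than ``n`` records raise.
    """
    if len(records) < n:
        raise ValueError(f"need >= {n} records, have {len(records)}")
    rng = np.random.default_rng(seed)
    areas = records["area_um2"].to_numpy(dtype=float)
    q1, q2 = np.quantile(areas, [1 / 3, 2 / 3])
    strata = [
        records.index[areas <= q1],
        records.index[(areas > q1) & (areas <= q2)],
        records.index[areas > q2],
    ]
    base, extra = divmod(n, 3)
    take = [base + (1 if i < extra else 0) for i in range(3)]
    # rebalance if a stratum is short
    for i in range(3):
        short = take[i] - len(strata[i])
        if short > 0:
            take[i] -= short
            take[(i + 1) % 3] += short
    chosen = []
    for idx, k in zip(strata, take):
        chosen.extend(rng.choice(np.asarray(idx), size=k, replace=False))
    return records.loc[sorted(chosen)]


def match_to_ground_truth(
    records: list,
    candidates: list,
    truth_islets: list[dict],
    pixel_size: float,
    max_dist_um: float = 50.0,
) -> list[tuple]:
    """Pair pipeline islet records with generator truth islets.

    A truth islet matches the candidate whose mask contains its centroid;
    failing that, the nearest candidate centroid within ``max_dist_um``.
    Returns (record, truth-dict) pairs; unpaired objects are dropped.
    """
    out = []
    used: set[int] = set()
    cand_centroids = []
    for cand in candidates:
        r_px, c_px = cand.centroid_px()
        cand_centroids.append((c_px * pixel_size, r_px * pixel_size))
    for t in truth_islets:
        tx, ty = t["centroid_um"] if isinstance(t, dict) else t.centroid_um
        hit = None
        for i, cand in enumerate(candidates):
            if i in used:
                continue
            r_px = int(round(ty / pixel_size))
            c_px = int(round(tx / pixel_size))
            sl = cand.bbox
            if (
                sl[0].start <= r_px < sl[0].stop
                and sl[1].start <= c_px < sl[1].stop
                and cand.mask[r_px - sl[0].start, c_px - sl[1].start]
            ):
                hit = i
                break
        if hit is None:
            dists = [
                np.hypot(cx - tx, cy - ty) if i not in used else np.inf
                for i, (cx, cy) in enumerate(cand_centroids)
            ]
            if dists and np.min(dists) < max_dist_um:
                hit = int(np.argmin(dists))
        if hit is not None:
            used.add(hit)
            out.append((records[hit], t))
    return out


def compare_to_reference(
    pipeline: pd.DataFrame,
    reference: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    alpha: float = 0.05,
    max_relative_deviation_pct: float = 5.0,
    id_column: str = "islet_id",
) -> ValidationReport:
    """Compare pipeline measurements with a matched reference, metric by metric.

    Records are matched on ``id_column`` (unmatched ids raise, listed).  For
    each metric the report holds the mean relative deviation
    ``100*mean(|pipe - ref| / ref)``, the bias, and a paired two-tailed t
    test of the differences; identical inputs trivially pass.
    """
    pipe = pipeline.set_index(id_column)
    ref = reference.set_index(id_column)
    unmatched = sorted(set(pipe.index).symmetric_difference(ref.index))
    if unmatched:
        raise ValueError(f"unmatched islet ids: {unmatched[:20]}")
    ref = ref.loc[pipe.index]
    rows = []
    for metric in metrics:
        a = pipe[metric].to_numpy(dtype=float)
        b = ref[metric].to_numpy(dtype=float)
        keep = np.isfinite(a) & np.isfinite(b) & (b != 0)
        a, b = a[keep], b[keep]
        rel = 100.0 * np.mean(np.abs(a - b) / np.abs(b)) if len(a) else float("nan")
        diff = a - b
        if len(a) >= 2 and np.std(diff, ddof=1) > 0:
            p = float(sps.ttest_rel(a, b).pvalue)
        else:
            p = 1.0  # identical (or constant-difference-free) measurements
        ok = (p >= alpha) and (rel <= max_relative_deviation_pct)
        rows.append(
            {
                "metric": metric,
                "n": len(a),
                "mean_rel_dev_pct": rel,
                "bias": float(diff.mean()) if len(a) else float("nan"),
                "p": p,
                "pass": ok,
            }
        )
    return ValidationReport(
        table=pd.DataFrame(rows),
        alpha=alpha,
        max_relative_deviation_pct=max_relative_deviation_pct,
    )
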