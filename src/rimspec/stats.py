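"""Group statistics: descriptives, one-way ANOVA, Tukey-Kramer HSD.

The classical between/within decomposition and the Tukey-Kramer studentized
range test are implemented here directly (they are the statistical machinery
of the analysis); scipy supplies only the F and studentized-range
distributions. Sample SDs use the n-1 denominator, p-values are two-sided,
and alpha = 0.05 throughout. No correction is applied across ratios or
layer families beyond Tukey within each comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

ALPHA = 0.05


def descriptive(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-group n, arithmetic mean and sample SD (NaN-flagged for n = 1)."""
    rows = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty group {name!r}")
        rows.append({
            "group": name, "n": int(vals.size), "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        })
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd"])


def one_way_anova(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA: F = MSB/MSW, p from F(k-1, N-k).

    Degenerate inputs: all values identical in every group gives (0, 1);
    zero within-group variance with distinct means gives (inf, 0).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, n_total - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def tukey_hsd(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tukey-Kramer adjusted pairwise p-values from the studentized range.

    q_ij = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)), df = N - k.
    The Kramer form handles unequal group sizes; for k = 2 the adjusted p
    equals the two-sided pooled-t p (q = sqrt(2)|t|).
    """
    if len(groups) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    names = list(groups)
    arrays = {n: np.asarray(v, dtype=float) for n, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs n >= 2")
    n_total = sum(a.size for a in arrays.values())
    k = len(names)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_w = n_total - k
    msw = ssw / df_w
    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            diff = abs(a.mean() - b.mean())
            if msw == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = diff / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            out[(names[i], names[j])] = p
    return out


def percent_difference(x: float, ref: float) -> float:
    """Signed percent difference 100*(x - ref)/ref."""
    if ref == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (x - ref) / ref


@dataclass
class GroupComparison:
    """Descriptives + ANOVA + Tukey for one family of named groups."""

    label: str
    table: pd.DataFrame             # group, n, mean, sd
    anova_f: float
    anova_p: float
    tukey: dict[tuple[str, str], float]
    alpha: float = ALPHA
    excluded: list[str] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        return list(self.table["group"])

    def tukey_p(self, a: str, b: str) -> float:
        if (a, b) in self.tukey:
            return self.tukey[(a, b)]
        return self.tukey[(b, a)]

    def mean(self, group: str) -> float:
        return float(self.table.set_index("group").loc[group, "mean"])

    def tukey_matrix(self) -> pd.DataFrame:
        g = self.groups
        m = pd.DataFrame(np.ones((len(g), len(g))), index=g, columns=g)
        for (a, b), p in self.tukey.items():
            m.loc[a, b] = m.loc[b, a] = p
        return m


def compare_groups(groups: dict[str, np.ndarray], label: str = "",
                   min_group_size: int = 2) -> GroupComparison:
    """Run descriptives + ANOVA + Tukey, excluding undersized groups."""
    kept = {}
    excluded = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < min_group_size:
            excluded.append(name)
            log.warning("group %r excluded from %r (n=%d < %d)",
                        name, label, vals.size, min_group_size)
        else:
            kept[name] = vals
    if len(kept) < 2:
        raise ValueError(f"comparison {label!r} needs >= 2 groups of n >= {min_group_size}")
    f, p = one_way_anova(kept)
    return GroupComparison(
        label=label, table=descriptive(kept), anova_f=f, anova_p=p,
        tukey=tukey_hsd(kept), excluded=excluded,
    )


def emit_report(comparisons: dict[str, GroupComparison], out_dir: str | Path,
                run_meta: dict | None = None) -> list[Path]:
    """Write one CSV per comparison (descriptives + p-matrix) and a run log.

    Each CSV carries the group rows (n, mean, sd) followed by the pairwise
    adjusted-p matrix; values round-trip through the CSV at full precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for key, comp in comparisons.items():
        safe = key.replace("/", "_per_").replace(" ", "_")
        path = out_dir / f"comparison_{safe}.csv"
        desc = comp.table.copy()
        desc.insert(0, "section", "descriptive")
        pm = comp.tukey_matrix().reset_index(names="group")
        pm.insert(0, "section", "tukey_p")
        head = pd.DataFrame([{
            "section": "anova", "group": "", "n": "",
            "mean": comp.anova_f, "sd": comp.anova_p,
        }])
        pd.concat([desc, head, pm], ignore_index=True).to_csv(path, index=False,
                                                              float_format="%.17g")
        written.append(path)
    index = pd.DataFrame(
        [{"comparison": k, "n_groups": len(v.groups),
          "anova_F": v.anova_f, "anova_p": v.anova_p}
         for k, v in comparisons.items()],
        columns=["comparison", "n_groups", "anova_F", "anova_p"])
    index_path = out_dir / "comparisons_index.csv"
    index.to_csv(index_path, index=False)  # header-only when nothing to report
    written.append(index_path)
    meta = dict(run_meta or {})
    meta.setdefault("alpha", ALPHA)
    meta["comparisons"] = list(comparisons)
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(meta, indent=2, default=str))
    written.append(log_path)
    return written
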