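"""Class-pair feature statistics and human-readable run reports.

Each feature/class-pair comparison is a two-sided test (Welch's t by
default; Mann–Whitney U for non-normal features) whose p-value is mapped to
a three-level category:

* ``O``        — significant difference, p < 0.001;
* ``TRIANGLE`` — slight difference, 0.001 ≤ p < 0.05;
* ``X``        — almost no difference, p ≥ 0.05.

The category intervals are half-open so the boundaries are unambiguous.
No multiple-testing correction is applied by default (the grid mirrors raw
per-pair marks); Holm correction over the grid is available via a flag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SignificanceCategory",
    "categorize",
    "pairwise_feature_test",
    "significance_grid",
    "render_report",
]


@dataclass(frozen=True)
class SignificanceCategory:
    symbol: str  # O | TRIANGLE | X
    p_value: float
    feature: str
    pair: tuple[str, str]


def categorize(p: float) -> str:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "O"
    if p < 0.05:
        return "TRIANGLE"
    return "X"


def _p_value(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "welch_t":
        if np.var(a) == 0 and np.var(b) == 0:
            # degenerate: both samples constant — identical means give no
            # evidence of a difference, unequal constants are a sure one
            return 1.0 if np.mean(a) == np.mean(b) else 0.0
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    elif test == "mann_whitney":
        try:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        except ValueError:  # all values identical
            p = 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(1.0 if np.isnan(p) else p)


def pairwise_feature_test(
    features: pd.DataFrame,
    feature: str,
    class_a: str,
    class_b: str,
    test: str = "welch_t",
) -> SignificanceCategory:
    """Two-sided comparison of one feature between two classes.

    ``features`` needs a ``class_label`` column and the named feature column;
    both classes must contribute at least 3 cells.
    """
    for cls in (class_a, class_b):
        if cls not in set(features["class_label"]):
            raise ValueError(f"class {cls!r} absent from the feature table")
    a = features.loc[features["class_label"] == class_a, feature].to_numpy(float)
    b = features.loc[features["class_label"] == class_b, feature].to_numpy(float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"need >= 3 cells per class, got {a.size} ({class_a}) and {b.size} ({class_b})"
        )
    p = _p_value(a, b, test)
    return SignificanceCategory(categorize(p), p, feature, (class_a, class_b))


def significance_grid(
    features: pd.DataFrame,
    pairs: list[tuple[str, str]],
    features_list: list[str],
    test: str = "welch_t",
    holm: bool = False,
) -> pd.DataFrame:
    """Full (feature × class-pair) grid of categories.

    Returns a long-format frame ``feature, class_a, class_b, p_value,
    category``.  With ``holm=True`` p-values are Holm-adjusted across the
    whole grid before categorisation.
    """
    rows = []
    for feat in features_list:
        for a, b in pairs:
            cat = pairwise_feature_test(features, feat, a, b, test=test)
            rows.append(
                {
                    "feature": feat,
                    "class_a": a,
                    "class_b": b,
                    "p_value": cat.p_value,
                    "category": cat.symbol,
                }
            )
    grid = pd.DataFrame(rows)
    if holm:
        p = grid["p_value"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        grid["p_value"] = adj
        grid["category"] = [categorize(v) for v in adj]
    return grid


def render_report(
    results_grids: dict[str, pd.DataFrame] | None,
    significance: pd.DataFrame | None,
    config_echo: dict | None = None,
) -> str:
    """Assemble a self-contained Markdown report with embedded CSV tables
    and a provenance block (config hash, seeds, library versions)."""
    import sklearn
    import scipy
    import skimage

    lines = ["# Cell discrimination run report", ""]
    warnings = []
    cfg = config_echo or {}
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    digest = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    lines += [
        "## Provenance",
        "",
        f"- config hash: `{digest}`",
        f"- seed(s): {cfg.get('seed', 'unspecified')}",
        f"- numpy {np.__version__}, scipy {scipy.__version__}, "
        f"scikit-learn {sklearn.__version__}, scikit-image {skimage.__version__}",
        "",
    ]
    if results_grids:
        lines += ["## Classification tasks", ""]
        for name, grid in results_grids.items():
            lines += [f"### {name}", "", "```csv", grid.to_csv(index=False).rstrip(), "```", ""]
    else:
        warnings.append("no classification results supplied")
    if significance is not None and len(significance):
        lines += [
            "## Feature significance grid",
            "",
            "```csv",
            significance.to_csv(index=False).rstrip(),
            "```",
            "",
        ]
    else:
        warnings.append("no significance grid supplied")
    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]
    return "\n".join(lines)
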