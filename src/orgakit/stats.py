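"""Two-sample rank-sum testing with significance-star annotation, and
report assembly.

The Mann-Whitney U test is exact (full enumeration of the null) for small
tie-free samples and falls back to the tie-corrected normal approximation
with continuity correction otherwise. Star labels follow the threshold
map: ns for 0.05 <= p, * for 0.01 < p < 0.05, ** for 0.001 < p < 0.01,
*** for 0.0001 < p < 0.001, **** for p < 0.0001; boundary values take the
less significant label.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "mann_whitney", "stars", "build_report"]

EXACT_MAX_N = 12  # combined sample size for exact enumeration

_STAR_THRESHOLDS = [
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
]


@dataclass(frozen=True)
class StatResult:
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    stars: str
    method: str  # "exact" | "normal-approximation"


def stars(p: float) -> str:
    """Significance-star label for a p-value (strict-inequality boundaries)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    for threshold, label in _STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum) test.

    Exact null enumeration when n1 + n2 <= 12 and the pooled data are
    tie-free; otherwise the normal approximation with tie and continuity
    corrections. Identical samples yield p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        return StatResult(n1 * n2 / 2.0, 1.0, n1, n2, "ns", "degenerate")
    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    p = float(min(res.pvalue, 1.0))
    return StatResult(float(res.statistic), p, n1, n2, stars(p), method)


def build_report(bundle: dict, version: str | None = None) -> dict:
    """Assemble the machine-readable run report.

    ``bundle`` maps stage names (onset, morphometry, motility,
    directionality, statistics) to their JSON-serializable outputs; absent
    stages are marked as such. At least one stage must be present.
    """
    known = ("onset", "morphometry", "motility", "directionality", "statistics")
    present = {k: v for k, v in bundle.items() if v is not None}
    if not present:
        raise ValueError("empty results bundle")
    unknown = set(bundle) - set(known) - {"parameters", "seed"}
    if unknown:
        raise ValueError(f"unknown report section(s): {sorted(unknown)}")
    if version is None:
        from . import __version__ as version
    report: dict = {"software_version": version}
    for key in ("parameters", "seed"):
        if key in bundle:
            report[key] = bundle[key]
    for stage in known:
        report[stage] = _jsonable(present[stage]) if stage in present else "absent"
    return report


def _jsonable(obj):
    """Recursively convert numpy and dataclass content to JSON-safe types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
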