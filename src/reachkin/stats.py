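"""Subject aggregation, exact Mann-Whitney comparison, and the group report.

Protocol: each participant performs three recorded repetitions of the
task; the per-subject value of every index is the mean over those
trials.  Groups (stroke vs control, six subjects each in the reference
study) are compared per index with a two-sided Mann-Whitney U test.  At
these sample sizes only an exact tail reaches bounds like p < 0.0002, so
for n_a + n_b <= 14 the null distribution of U is enumerated over all
C(n_a+n_b, n_a) group-label assignments (ties handled by midranks);
larger samples fall back to the normal approximation with tie
correction.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indexes import TrialIndexes

__all__ = [
    "SubjectSummary",
    "MannWhitneyResult",
    "EXACT_LIMIT",
    "REPORT_LAYOUT",
    "summarize_subject",
    "exact_mann_whitney",
    "compare_groups",
    "load_clinical_scores",
]

#: Exact enumeration is used whenever the pooled sample is this size or less.
EXACT_LIMIT = 14


@dataclass
class SubjectSummary:
    """Per-subject mean of every index over that subject's trials."""

    subject_id: str
    group: str
    values: dict[str, float]
    n_trials: int


def summarize_subject(
    trials: list[TrialIndexes], subject_id: str = "anonymous", group: str = "control"
) -> SubjectSummary:
    """Arithmetic mean per index field over a subject's trials (order-free).

    Movement-unit means may be non-integer."""
    if not trials:
        raise ValueError("summarize_subject needs at least one trial")
    records = [t.as_dict() for t in trials]
    keys = records[0].keys()
    means = {k: float(np.mean([r[k] for r in records])) for k in keys}
    return SubjectSummary(subject_id=subject_id, group=group, values=means, n_trials=len(records))


# ---------------------------------------------------------------------------
# exact Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # min(U_a, U_b) from midrank-based ranking
    p: float  # two-sided
    exact: bool


@lru_cache(maxsize=64)
def _index_combinations(n: int, k: int) -> np.ndarray:
    return np.array(list(combinations(range(n), k)), dtype=np.intp)


def exact_mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U = min(U_a, U_b) from midranks.  For pooled n <= EXACT_LIMIT the
    one-sided tail counts label assignments with U_a <= U over all
    C(n, n_a) assignments and is doubled (capped at 1); this handles
    ties exactly under the permutation null.  Larger samples use the
    normal approximation with tie correction."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    ua = float(ranks[:na].sum() - na * (na + 1) / 2)
    ub = float(na * nb - ua)
    u = min(ua, ub)

    if na + nb <= EXACT_LIMIT:
        combos = _index_combinations(na + nb, na)
        ua_all = ranks[combos].sum(axis=1) - na * (na + 1) / 2
        tail = int(np.sum(ua_all <= u + 1e-9))
        p = min(1.0, 2.0 * tail / comb(na + nb, na))
        return MannWhitneyResult(u=u, p=p, exact=True)

    if np.all(pooled == pooled[0]):
        return MannWhitneyResult(u=u, p=1.0, exact=False)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(u=u, p=float(res.pvalue), exact=False)


# ---------------------------------------------------------------------------
# group report
# ---------------------------------------------------------------------------

#: Report rows in task order: (phase label, index key, printable name).
REPORT_LAYOUT: list[tuple[str, str, str]] = [
    ("reaching", "rg_duration_s", "Duration (s)"),
    ("reaching", "arm_elongation_pct", "Arm elongation (%)"),
    ("reaching", "elbow_rom_deg", "Elbow ROM (deg)"),
    ("reaching", "trunk_forward_inclination_pct", "Trunk forward inclination (%)"),
    ("reaching", "trunk_axial_rotation_pct", "Trunk axial rotation (%)"),
    ("reaching", "mouth_forward_displacement_mm", "Mouth forward displacement (mm)"),
    ("reaching", "nmu_reaching", "Number of movement units"),
    ("bringing", "bgm_duration_s", "Duration (s)"),
    ("bringing", "arm_contribution_bgm_pct", "Arm contribution (%)"),
    ("bringing", "mouth_backward_displacement_mm", "Mouth backward displacement (mm)"),
    ("bringing", "nmu_bringing", "Number of movement units"),
    ("putting_back", "tbgt_duration_s", "Duration (s)"),
    ("putting_back", "arm_contribution_tbgt_pct", "Arm contribution (%)"),
    ("reaching_and_bringing", "nmu_reaching_and_bringing", "Number of movement units"),
    ("reaching_and_bringing", "mouth_overall_displacement_mm", "Mouth overall displacement (mm)"),
]


def compare_groups(
    patients: list[SubjectSummary], controls: list[SubjectSummary]
) -> pd.DataFrame:
    """Per-index group comparison table.

    One row per index in task order: patients' median and range,
    controls' median and range, U statistic, two-sided p, and whether
    the exact enumeration was used.  Medians use the midpoint convention
    for even n; invariant under subject reordering within a group."""
    if not patients or not controls:
        raise ValueError("both groups must be non-empty")
    rows = []
    for phase, key, label in REPORT_LAYOUT:
        pa = np.array([s.values[key] for s in patients], dtype=float)
        co = np.array([s.values[key] for s in controls], dtype=float)
        res = exact_mann_whitney(pa, co)
        rows.append(
            {
                "phase": phase,
                "index": label,
                "patients_median": float(np.median(pa)),
                "patients_min": float(pa.min()),
                "patients_max": float(pa.max()),
                "controls_median": float(np.median(co)),
                "controls_min": float(co.min()),
                "controls_max": float(co.max()),
                "U": res.u,
                "p_value": res.p,
                "exact": res.exact,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical metadata
# ---------------------------------------------------------------------------


def load_clinical_scores(path: str | Path | None = None) -> pd.DataFrame:
    """Load a clinical-score table (columns id, ..., barthel, fma).

    Without a path, returns the packaged six-patient reference stroke
    cohort (subacute hemiparetic patients; Barthel 0-100, FMA-UE 0-66)."""
    if path is None:
        source = importlib.resources.files("reachkin.data") / "stroke_cohort_clinical.csv"
        with importlib.resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    for col in ("id", "barthel", "fma"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    return df
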