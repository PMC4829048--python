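"""Evaluation experiments: sampling-intensity sweep, precision metrics,
edge-effect spatial subsampling, and the supporting statistics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    CreInputs,
    cre_estimate,
    DAM_MORTALITY,
    FS_THRESHOLD,
    SIRE_MORTALITY,
)
from .genotyping import IndividualTable
from .parentage import ParentageConfig, pedigree_from_assignments, reconstruct_pedigree
from .relatedness import allele_frequencies, lr_matrix


def prp(estimate: float, ci_low: float, ci_high: float) -> int:
    """Percentage relative precision: CI half-width as % of the estimate."""
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    if not (ci_low <= estimate <= ci_high):
        raise ValueError("estimate must lie inside [ci_low, ci_high]")
    return int(math.floor(100.0 * (ci_high - ci_low) / 2.0 / estimate + 0.5))


def two_prop_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sample z-test for proportions with the pooled variance estimate."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def chisq_homogeneity(counts: Sequence[int], ns: Sequence[int]):
    """Pearson chi-square for homogeneity of proportions across groups.

    Builds the groups x (event, no-event) contingency table from per-group
    event counts and totals; df = groups - 1.  Expected cells < 1 set a
    warning flag in the returned tuple (chi2, df, p, flagged).
    """
    counts = np.asarray(counts, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if np.any(ns <= 0):
        raise ValueError("group totals must be positive")
    table = np.stack([counts, ns - counts], axis=1)
    if np.all(counts == 0) or np.all(counts == ns):
        return 0.0, len(ns) - 1, 1.0, False
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    flagged = bool(np.any(expected < 1.0))
    if flagged:
        warnings.warn("expected cell count below 1; chi-square approximation poor",
                      stacklevel=2)
    return float(chi2), int(dof), float(p), flagged


def one_sample_t(values: Sequence[float], mu: float):
    """One-sample two-sided t test; (t, df, p)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    if np.std(values, ddof=1) == 0:
        if values[0] == mu:
            return 0.0, values.size - 1, 1.0
        return float("inf") if values[0] > mu else float("-inf"), values.size - 1, 0.0
    res = stats.ttest_1samp(values, mu)
    return float(res.statistic), int(values.size - 1), float(res.pvalue)


# --------------------------------------------------------------------------
# sampling-intensity sweep
# --------------------------------------------------------------------------


@dataclass
class IntensitySweepResult:
    """Replicate population estimates per sampling-intensity level."""

    levels: list[float]
    estimates: dict[float, list[float]]
    n_ref: float

    def cv(self, level: float) -> float:
        vals = np.asarray(self.estimates[level], dtype=float)
        if vals.size < 2:
            raise ValueError("CV requires at least two replicates")
        return float(np.std(vals, ddof=1) / np.mean(vals))

    def pct_diff(self, level: float) -> float:
        """100 * |N_ref - mean| / mean: deficit relative to the estimate."""
        mean = float(np.mean(self.estimates[level]))
        return 100.0 * abs(self.n_ref - mean) / mean

    def mean(self, level: float) -> float:
        return float(np.mean(self.estimates[level]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "level": lv,
                    "n_draw": len(self.estimates[lv]) and int(round(lv * self.n_ref)),
                    "mean_estimate": self.mean(lv),
                    "cv": self.cv(lv),
                    "pct_diff": self.pct_diff(lv),
                }
                for lv in self.levels
            ]
        )


def make_cre_engine(
    parentage_config: ParentageConfig | None = None,
    strategy: str = "nonbreeder_fraction",
    m_f: float = DAM_MORTALITY,
    m_m: float = SIRE_MORTALITY,
    fs_threshold: float = FS_THRESHOLD,
    with_relatedness: bool = True,
) -> Callable[[IndividualTable], float]:
    """Engine that reruns pedigree reconstruction + CRE on a subset."""

    cfg = parentage_config or ParentageConfig()

    def engine(table: IndividualTable) -> float:
        if len(table) < 2:
            return float(len(table))
        freqs = allele_frequencies(table.genotypes)
        ped = reconstruct_pedigree(table, freqs, cfg)
        rel = lr_matrix(table, freqs) if with_relatedness else None
        inputs = CreInputs.from_pedigree(
            ped, rel, m_f=m_f, m_m=m_m, fs_threshold=fs_threshold
        )
        return float(cre_estimate(inputs, strategy=strategy).n_hat)

    return engine


def make_truth_engine(
    truth_assignments: pd.DataFrame,
    strategy: str = "nonbreeder_fraction",
    m_f: float = DAM_MORTALITY,
    m_m: float = SIRE_MORTALITY,
) -> Callable[[IndividualTable], float]:
    """Engine using the known pedigree restricted to the drawn subset.

    Isolates the estimator's sampling behaviour from reconstruction error.
    """
    truth = truth_assignments.set_index("offspring_id")

    def engine(table: IndividualTable) -> float:
        present = set(table.latent_ids if table.latent_ids else table.ids)
        rows = []
        for iid in sorted(present):
            dam = sire = None
            if iid in truth.index:
                trow = truth.loc[iid]
                dam = trow["dam_id"] if trow["dam_id"] in present else None
                sire = trow["sire_id"] if trow["sire_id"] in present else None
            rows.append({"offspring_id": iid, "dam_id": dam, "sire_id": sire})
        ped = pedigree_from_assignments(pd.DataFrame(rows))
        inputs = CreInputs.from_pedigree(ped, None, m_f=m_f, m_m=m_m)
        return float(cre_estimate(inputs, strategy=strategy).n_hat)

    return engine


def sampling_intensity_sweep(
    individuals: IndividualTable,
    engine: Callable[[IndividualTable], float],
    n_ref: float,
    levels: Sequence[float],
    n_reps: int = 10,
    seed: int | None = None,
) -> IntensitySweepResult:
    """Rerun the estimator on random draws at each sampling-intensity level.

    Per level, ``round(level * n_ref)`` individuals are drawn uniformly
    without replacement and the engine (reconstruction + estimation, or the
    truth-restricted estimator) is applied to each of ``n_reps`` replicates.
    """
    if n_ref <= 0:
        raise ValueError("reference population size must be positive")
    if n_reps < 2:
        raise ValueError("need at least two replicates for the CV")
    levels = list(levels)
    if any(not (0 < lv <= 1) for lv in levels):
        raise ValueError("levels must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(individuals)
    estimates: dict[float, list[float]] = {}
    for lv in levels:
        n_draw = int(round(lv * n_ref))
        if n_draw > n:
            raise ValueError(
                f"level {lv} requests {n_draw} individuals but only {n} are available"
            )
        if n_draw < 1:
            raise ValueError(f"level {lv} draws no individuals")
        vals = []
        for _ in range(n_reps):
            idx = rng.choice(n, size=n_draw, replace=False)
            vals.append(float(engine(individuals.subset(np.sort(idx)))))
        estimates[lv] = vals
    return IntensitySweepResult(levels=levels, estimates=estimates, n_ref=float(n_ref))


# --------------------------------------------------------------------------
# edge-effect spatial subsampling
# --------------------------------------------------------------------------


@dataclass
class EdgeSubsets:
    """Core and border subsets of individuals by proximity rules."""

    center_point: tuple[float, float]
    subsets: dict[str, list[str]]  # core / north / south / east / west
    n: int
    overlapping: bool = False
    degenerate: bool = False


def edge_subsets(individuals: IndividualTable, n: int) -> EdgeSubsets:
    """Select the n individuals nearest the center and each border.

    The center point is the median center of the individual median centers;
    borders are the edges of the bounding rectangle of those centers
    (west = smallest x, east = largest x, north = largest y, south =
    smallest y).  Ties break by individual id.
    """
    ids = list(individuals.ids)
    centers = individuals.centers
    if n > len(ids):
        raise ValueError("n exceeds the population size")
    cx = float(np.median(centers[:, 0]))
    cy = float(np.median(centers[:, 1]))

    def take(keys: np.ndarray) -> list[str]:
        order = sorted(range(len(ids)), key=lambda i: (keys[i], ids[i]))
        return [ids[i] for i in order[:n]]

    d2 = (centers[:, 0] - cx) ** 2 + (centers[:, 1] - cy) ** 2
    subsets = {
        "core": take(d2),
        "west": take(centers[:, 0]),
        "east": take(-centers[:, 0]),
        "north": take(-centers[:, 1]),
        "south": take(centers[:, 1]),
    }
    degenerate = bool(np.allclose(centers, centers[0])) or n == len(ids)
    names = list(subsets)
    overlapping = any(
        set(subsets[a]) & set(subsets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    )
    return EdgeSubsets(
        center_point=(cx, cy),
        subsets=subsets,
        n=n,
        overlapping=overlapping,
        degenerate=degenerate,
    )


def sex_separated_edge_subsets(individuals: IndividualTable, n: int) -> dict[str, EdgeSubsets]:
    """The same nearest-to-edge rule applied to each sex separately."""
    out = {}
    for sx in ("F", "M"):
        idx = np.nonzero(individuals.sex == sx)[0]
        out[sx] = edge_subsets(individuals.subset(idx), n)
    return out


def dyad_completeness(
    subset_ids: Sequence[str],
    assignments: pd.DataFrame,
    offspring_sex: dict[str, str] | None = None,
    sex_filter: str | None = None,
) -> float:
    """Parent-offspring pairs fully inside the subset, per subset member.

    ``sex_filter`` restricts to "mother_daughter" (dam links with female
    offspring) or "father_son" (sire links with male offspring); offspring
    sexes must then be supplied.
    """
    members = set(subset_ids)
    if not members:
        raise ValueError("subset must be non-empty")
    count = 0
    for row in assignments.itertuples():
        off = row.offspring_id
        for parent, link in ((row.dam_id, "dam"), (row.sire_id, "sire")):
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                continue
            if off not in members or parent not in members:
                continue
            if sex_filter == "mother_daughter":
                if link != "dam" or offspring_sex is None or offspring_sex.get(off) != "F":
                    continue
            elif sex_filter == "father_son":
                if link != "sire" or offspring_sex is None or offspring_sex.get(off) != "M":
                    continue
            elif sex_filter is not None:
                raise ValueError(f"unknown sex_filter {sex_filter!r}")
            count += 1
    return count / len(members)
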