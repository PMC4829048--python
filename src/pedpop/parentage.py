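"""Likelihood-based parentage assignment and pedigree reconstruction.

Replaces an MCMC pedigree sampler with a deterministic per-offspring
maximum-likelihood engine: candidate parents are screened by Mendelian
exclusion counts, each focal individual's best configuration (triad, dam- or
sire-only dyad, or no sampled parent) is scored against the "both parents
unsampled" null, and accepted assignments are made globally consistent
(acyclic, sexes respected) by greedy resolution in decreasing posterior
odds.

The genotyping error model: each observed call is correct with probability
1 - eps, otherwise uniform over the other two genotype calls.  Priors over
configurations come from the candidate-pool sizes relative to the
approximate population ceilings Nf_max / Nm_max: the prior that a specific
sampled female is the dam is 1/Nf_max, and the prior that the dam is
unsampled is 1 - n_F/Nf_max.

Without ages, the direction of an isolated parent-offspring dyad is
unidentifiable (the likelihood ratio is symmetric); such near-tied two-cycles
are broken toward the candidate claimed as a parent by more focal
individuals, which resolves multi-offspring families correctly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotyping import IndividualTable
from .panel import MISSING

#: empirically determined per-call error rates from the two study datasets
LOW_ERROR_RATE = 1.538e-4
DEFAULT_ERROR_RATE = 0.01

_LOG_FLOOR = 1e-300
_TIE_TOL = 1e-3  # log-likelihoods within this are reported as ambiguous ties
# Without ages the direction of a parent-offspring dyad is unidentifiable up
# to the weak asymmetry injected by typing error; mutual claims closer than
# this log-odds window are resolved structurally (see _resolve_mutual_claims)
_MUTUAL_WINDOW = 10.0


@dataclass(frozen=True)
class ParentageConfig:
    typing_error: float = DEFAULT_ERROR_RATE
    nf_max: int | None = None  # ceiling on the number of candidate dams
    nm_max: int | None = None
    min_posterior_odds: float = 10.0
    use_sex: bool = True
    use_age: bool = False  # hook only; no age data in the noninvasive setting
    max_pool: int = 30  # cap on per-focal candidate pools entering the trio search

    def __post_init__(self) -> None:
        if not 0.0 <= self.typing_error < 0.5:
            raise ValueError("typing_error must be in [0, 0.5)")
        for name in ("nf_max", "nm_max"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


def mendelian_incompatibilities(off_g, parent_g) -> int:
    """Count co-called loci where parent and offspring share no allele.

    For biallelic loci that means opposing homozygotes (AA vs BB).
    """
    a = np.asarray(off_g, dtype=int)
    b = np.asarray(parent_g, dtype=int)
    both = (a != MISSING) & (b != MISSING)
    return int(np.sum(both & (((a == 2) & (b == 0)) | ((a == 0) & (b == 2)))))


def _error_matrix(eps: float) -> np.ndarray:
    E = np.full((3, 3), eps / 2.0)
    np.fill_diagonal(E, 1.0 - eps)
    return E  # E[obs, true]


def _hw(p: np.ndarray) -> np.ndarray:
    q = 1.0 - p
    return np.stack([q * q, 2 * p * q, p * p], axis=-1)  # (..., g)


def _transmit(g_par: np.ndarray) -> np.ndarray:
    """Probability of transmitting allele A for each parental dosage."""
    return np.asarray(g_par) / 2.0


def _parent_posterior(p: np.ndarray, eps: float) -> np.ndarray:
    """w[l, g_obs, g_true]: posterior of a parent's true genotype given its
    observed call, under a Hardy-Weinberg prior and the error model.

    Parents' calls carry the same per-call error as offspring calls; a
    likelihood that treats observed parental genotypes as exact would let a
    single parental miscall at a forced-transmission locus veto a true trio.
    At eps = 0 this collapses to the identity.
    """
    hw = _hw(p)  # (L, g_true)
    E = _error_matrix(eps)
    w = hw[:, None, :] * E[None, :, :]
    return w / w.sum(axis=2, keepdims=True)


def _mendel_single(p: np.ndarray) -> np.ndarray:
    """M[l, g_par, g_off]: true offspring genotype given one true parent,
    the other drawn from Hardy-Weinberg."""
    L = p.size
    M = np.empty((L, 3, 3))
    for gp in range(3):
        t = gp / 2.0
        M[:, gp, :] = np.stack(
            [(1 - t) * (1 - p), t * (1 - p) + (1 - t) * p, t * p], axis=-1
        )
    return M


_MENDEL_TRIO = np.empty((3, 3, 3))
for _gd in range(3):
    for _gs in range(3):
        _td, _ts = _gd / 2.0, _gs / 2.0
        _MENDEL_TRIO[_gd, _gs] = (
            (1 - _td) * (1 - _ts),
            _td * (1 - _ts) + (1 - _td) * _ts,
            _td * _ts,
        )
del _gd, _gs, _td, _ts


def _single_table(p: np.ndarray, eps: float) -> np.ndarray:
    """T[l, g_par_obs, g_off_obs]: P(observed offspring call | observed
    parent call), marginalizing both calls' errors and the unknown mate."""
    E = _error_matrix(eps)
    w = _parent_posterior(p, eps)
    obs_dist = _mendel_single(p) @ E.T  # (L, g_par_true, g_off_obs)
    return np.einsum("lpt,lto->lpo", w, obs_dist)


def _trio_table(p: np.ndarray, eps: float) -> np.ndarray:
    """T[l, g_dam_obs, g_sire_obs, g_off_obs] under Mendelian transmission,
    marginalizing per-call error in all three observed genotypes."""
    E = _error_matrix(eps)
    w = _parent_posterior(p, eps)
    obs = _MENDEL_TRIO @ E.T  # (g_dam_true, g_sire_true, g_off_obs)
    return np.einsum("lde,lsf,efo->ldso", w, w, obs)


def _null_table(p: np.ndarray, eps: float) -> np.ndarray:
    """N[l, g_obs]: P(observed call | both parents unsampled, HW)."""
    E = _error_matrix(eps)
    return _hw(p) @ E.T


def trio_loglik(off_g, dam_g, sire_g, freqs, eps: float = 0.0) -> float:
    """Log-likelihood of the offspring calls given both parental genotypes.

    Loci with any missing call in the trio are skipped.  -inf is possible at
    eps = 0 when a Mendelian exclusion exists.
    """
    off = np.asarray(off_g, dtype=int)
    dam = np.asarray(dam_g, dtype=int)
    sire = np.asarray(sire_g, dtype=int)
    p = np.asarray(freqs, dtype=float)
    mask = (off != MISSING) & (dam != MISSING) & (sire != MISSING)
    T = _trio_table(p, eps)
    idx = np.nonzero(mask)[0]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(T[idx, dam[idx], sire[idx], off[idx]])))


def single_parent_loglik(off_g, parent_g, freqs, eps: float = 0.0) -> float:
    """Log-likelihood with one parent known, the other integrated over HW."""
    off = np.asarray(off_g, dtype=int)
    par = np.asarray(parent_g, dtype=int)
    p = np.asarray(freqs, dtype=float)
    mask = (off != MISSING) & (par != MISSING)
    T = _single_table(p, eps)
    idx = np.nonzero(mask)[0]
    with np.errstate(divide="ignore"):
        return float(np.sum(np.log(T[idx, par[idx], off[idx]])))


CATEGORY_TRIAD = "triad"
CATEGORY_DYAD_DAM = "dyad_dam"
CATEGORY_DYAD_SIRE = "dyad_sire"
CATEGORY_NONE = "none"


@dataclass
class PedigreeResult:
    """Reconstructed sampled pedigree with the Table-1-style categories."""

    assignments: pd.DataFrame  # offspring_id, dam_id, sire_id, category, log_odds, ambiguous
    n_s: int
    n_triads: int
    n_dyads: int
    n_unassigned: int
    breeders: set[str]
    dam_sire_ratio: float
    distinct_dams: int
    distinct_sires: int

    @property
    def b_s(self) -> int:
        return len(self.breeders)

    @property
    def breeder_proportion(self) -> float:
        return self.b_s / self.n_s if self.n_s else float("nan")

    @property
    def dyads(self) -> list[tuple[str, str, str]]:
        """(offspring_id, known_parent_id, known_parent_sex) per dyad."""
        out = []
        for row in self.assignments.itertuples():
            if row.category == CATEGORY_DYAD_DAM:
                out.append((row.offspring_id, row.dam_id, "F"))
            elif row.category == CATEGORY_DYAD_SIRE:
                out.append((row.offspring_id, row.sire_id, "M"))
        return out

    def summary(self) -> str:
        lines = [
            "Pedigree reconstruction",
            "=" * 40,
            f"Individuals sampled (N_s)      {self.n_s:>8d}",
            f"Triads (both parents)          {self.n_triads:>8d}",
            f"Dyads (one parent)             {self.n_dyads:>8d}",
            f"No identified parent           {self.n_unassigned:>8d}",
            f"Known breeders (B_s)           {self.b_s:>8d}",
            f"Proportion of breeders         {self.breeder_proportion:>8.2f}",
            f"Ratio of dams:sires            {self.dam_sire_ratio:>8.2f}",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.assignments.to_csv(path, index=False)


@dataclass
class _Record:
    focal: int
    dam: int | None
    sire: int | None
    log_odds: float
    ambiguous: bool


def _llr_dyad_matrix(G: np.ndarray, p: np.ndarray, eps: float) -> np.ndarray:
    """LLR[k, j] = log P(focal k's calls | parent j) - log P(. | null)."""
    n, L = G.shape
    called = G != MISSING
    single = np.log(np.maximum(_single_table(p, eps), _LOG_FLOOR))
    null = np.log(np.maximum(_null_table(p, eps), _LOG_FLOOR))
    table = single - null[:, None, :]  # (L, g_par, g_off)
    off_hot = np.zeros((n, L, 3))
    par_hot = np.zeros((n, L, 3))
    rows, cols = np.nonzero(called)
    off_hot[rows, cols, G[rows, cols]] = 1.0
    par_hot[rows, cols, G[rows, cols]] = 1.0
    llr = np.zeros((n, n))
    for gp in range(3):
        for go in range(3):
            llr += (off_hot[:, :, go] * table[:, gp, go]) @ par_hot[:, :, gp].T
    return llr


def reconstruct_pedigree(
    individuals: IndividualTable,
    freqs: np.ndarray | None = None,
    config: ParentageConfig | None = None,
) -> PedigreeResult:
    """Assign a dam and/or sire to every individual where the evidence allows.

    Candidates are screened per pair by allowing at most ceil(2 * eps * L)
    Mendelian exclusions over the L co-called loci, the best configuration is
    gated on its posterior odds against the both-parents-unsampled null, and
    the union of accepted assignments is made acyclic.
    """
    from .relatedness import allele_frequencies

    cfg = config or ParentageConfig()
    G = np.asarray(individuals.genotypes, dtype=np.int8)
    n, L = G.shape
    ids = list(individuals.ids)
    sex = np.asarray(individuals.sex, dtype="<U1")
    if freqs is None:
        freqs = allele_frequencies(G)
    p = np.asarray(freqs, dtype=float)
    eps = cfg.typing_error

    if n == 0:
        return _empty_result()

    called = G != MISSING
    hom_a = (G == 2).astype(np.int32)
    hom_b = (G == 0).astype(np.int32)
    excl = hom_a @ hom_b.T + hom_b @ hom_a.T
    co_called = called.astype(np.int32) @ called.T.astype(np.int32)
    allowed = np.ceil(2.0 * eps * co_called)

    if cfg.use_sex:
        female_idx = np.nonzero(sex == "F")[0]
        male_idx = np.nonzero(sex == "M")[0]
    else:
        female_idx = male_idx = np.arange(n)
    n_f, n_m = len(female_idx), len(male_idx)
    nf_max = cfg.nf_max if cfg.nf_max is not None else max(2 * n_f, 1)
    nm_max = cfg.nm_max if cfg.nm_max is not None else max(2 * n_m, 1)
    p_f = float(np.clip(n_f / nf_max, 0.01, 0.99))
    p_m = float(np.clip(n_m / nm_max, 0.01, 0.99))
    # log prior odds of each configuration against the null
    prior_dyad_dam = math.log(1.0 / nf_max) - math.log(1.0 - p_f)
    prior_dyad_sire = math.log(1.0 / nm_max) - math.log(1.0 - p_m)
    prior_trio = prior_dyad_dam + prior_dyad_sire

    llr_dyad = _llr_dyad_matrix(G, p, eps)
    trio_t = np.log(np.maximum(_trio_table(p, eps), _LOG_FLOOR))
    null_t = np.log(np.maximum(_null_table(p, eps), _LOG_FLOOR))

    min_log_odds = math.log(cfg.min_posterior_odds)
    records: list[_Record] = []
    for k in range(n):
        pools = {}
        for role, cand_idx in (("F", female_idx), ("M", male_idx)):
            cand = cand_idx[cand_idx != k]
            ok = excl[k, cand] <= allowed[k, cand]
            ok &= co_called[k, cand] > 0
            cand = cand[ok]
            cap = nf_max if role == "F" else nm_max
            if len(cand) > cap:
                warnings.warn(
                    f"candidate pool for {ids[k]} exceeds the ceiling; "
                    "truncating by likelihood rank",
                    stacklevel=2,
                )
                cand = cand[np.argsort(-llr_dyad[k, cand])[:cap]]
            if len(cand) > cfg.max_pool:
                cand = cand[np.argsort(-llr_dyad[k, cand])[: cfg.max_pool]]
            pools[role] = cand

        best: tuple[float, int | None, int | None] = (0.0, None, None)  # null
        ambiguous = False

        def rank(cand: np.ndarray) -> np.ndarray:
            # deterministic: likelihood desc, then id asc
            order = sorted(range(len(cand)), key=lambda t: (-llr_dyad[k, cand[t]], ids[cand[t]]))
            return cand[np.array(order, dtype=int)] if len(cand) else cand

        dams = rank(pools["F"])
        sires = rank(pools["M"])

        if len(dams):
            lo = llr_dyad[k, dams[0]] + prior_dyad_dam
            if lo > best[0]:
                best = (lo, int(dams[0]), None)
            if len(dams) > 1 and llr_dyad[k, dams[0]] - llr_dyad[k, dams[1]] < _TIE_TOL:
                ambiguous = True
        if len(sires):
            lo = llr_dyad[k, sires[0]] + prior_dyad_sire
            if lo > best[0]:
                best = (lo, None, int(sires[0]))
            if len(sires) > 1 and llr_dyad[k, sires[0]] - llr_dyad[k, sires[1]] < _TIE_TOL:
                ambiguous = True

        if len(dams) and len(sires):
            off = G[k]
            m_off = off != MISSING
            best_trio = (-np.inf, None, None)
            for di in dams:
                m_d = m_off & (G[di] != MISSING)
                for sj in sires:
                    if sj == di:
                        continue
                    m = np.nonzero(m_d & (G[sj] != MISSING))[0]
                    llr = float(
                        np.sum(trio_t[m, G[di, m], G[sj, m], off[m]])
                        - np.sum(null_t[m, off[m]])
                    )
                    key = (llr, ids[int(di)], ids[int(sj)])
                    if llr > best_trio[0] or (
                        llr == best_trio[0]
                        and best_trio[1] is not None
                        and key[1:] < (ids[best_trio[1]], ids[best_trio[2]])
                    ):
                        if best_trio[0] > -np.inf and llr - best_trio[0] < _TIE_TOL:
                            ambiguous = True
                        best_trio = (llr, int(di), int(sj))
            if best_trio[1] is not None:
                lo = best_trio[0] + prior_trio
                if lo > best[0]:
                    best = (lo, best_trio[1], best_trio[2])

        if best[1] is not None or best[2] is not None:
            if best[0] > min_log_odds:
                records.append(
                    _Record(
                        focal=k,
                        dam=best[1],
                        sire=best[2],
                        log_odds=best[0],
                        ambiguous=ambiguous,
                    )
                )

    # ---- global consistency: greedy acyclic resolution -------------------
    claims = np.zeros(n, dtype=int)
    for rec in records:
        if rec.dam is not None:
            claims[rec.dam] += 1
        if rec.sire is not None:
            claims[rec.sire] += 1

    _resolve_mutual_claims(records, claims, ids)
    records = [r for r in records if r.dam is not None or r.sire is not None]

    def claim_score(rec: _Record) -> int:
        s = 0
        if rec.dam is not None:
            s = max(s, claims[rec.dam])
        if rec.sire is not None:
            s = max(s, claims[rec.sire])
        return s

    records.sort(key=lambda r: (-round(r.log_odds, 3), -claim_score(r), ids[r.focal]))

    dag = nx.DiGraph()
    dag.add_nodes_from(range(n))
    final_dam: dict[int, int] = {}
    final_sire: dict[int, int] = {}
    odds: dict[int, float] = {}
    amb: dict[int, bool] = {}
    for rec in records:
        placed = False
        for parent, store in ((rec.dam, final_dam), (rec.sire, final_sire)):
            if parent is None:
                continue
            if dag.has_node(parent) and nx.has_path(dag, rec.focal, parent):
                continue  # would create a cycle; drop this slot
            dag.add_edge(parent, rec.focal)
            store[rec.focal] = parent
            placed = True
        if placed:
            odds[rec.focal] = rec.log_odds
            amb[rec.focal] = rec.ambiguous

    rows = []
    for k in range(n):
        dam = final_dam.get(k)
        sire = final_sire.get(k)
        if dam is not None and sire is not None:
            cat = CATEGORY_TRIAD
        elif dam is not None:
            cat = CATEGORY_DYAD_DAM
        elif sire is not None:
            cat = CATEGORY_DYAD_SIRE
        else:
            cat = CATEGORY_NONE
        rows.append(
            {
                "offspring_id": ids[k],
                "dam_id": ids[dam] if dam is not None else None,
                "sire_id": ids[sire] if sire is not None else None,
                "category": cat,
                "log_odds": odds.get(k, np.nan),
                "ambiguous": amb.get(k, False),
            }
        )
    assignments = pd.DataFrame(rows)
    return _summarize(assignments)


def _resolve_mutual_claims(records: list[_Record], claims: np.ndarray, ids) -> None:
    """Resolve A-claims-B-as-parent vs B-claims-A-as-parent conflicts.

    A real pair cannot be each other's parent, so exactly one claim of a
    mutual pair must go.  When the posterior odds differ by more than the
    mutual window the weaker claim is dropped; otherwise the structural
    signal decides: the individual claimed as a parent by more focal
    individuals keeps its parenthood (a dam with several sampled offspring
    is claimed by all of them, while an offspring is claimed only by its
    parent).  Remaining ties fall back to odds, then to id order.
    """
    by_focal = {rec.focal: rec for rec in records}

    def drop(rec: _Record, parent: int) -> None:
        if rec.dam == parent:
            rec.dam = None
        if rec.sire == parent:
            rec.sire = None
        rec.ambiguous = True

    for rec in records:
        for parent in (rec.dam, rec.sire):
            if parent is None:
                continue
            other = by_focal.get(parent)
            if other is None or rec.focal not in (other.dam, other.sire):
                continue
            # mutual claim between rec.focal and parent
            if abs(rec.log_odds - other.log_odds) >= _MUTUAL_WINDOW:
                if rec.log_odds > other.log_odds:
                    drop(other, rec.focal)
                else:
                    drop(rec, parent)
                continue
            key_rec = (claims[parent], rec.log_odds, ids[parent])
            key_other = (claims[rec.focal], other.log_odds, ids[rec.focal])
            if key_rec >= key_other:
                drop(other, rec.focal)
            else:
                drop(rec, parent)


def _empty_result() -> PedigreeResult:
    cols = ["offspring_id", "dam_id", "sire_id", "category", "log_odds", "ambiguous"]
    return PedigreeResult(
        assignments=pd.DataFrame(columns=cols),
        n_s=0,
        n_triads=0,
        n_dyads=0,
        n_unassigned=0,
        breeders=set(),
        dam_sire_ratio=float("nan"),
        distinct_dams=0,
        distinct_sires=0,
    )


def _summarize(assignments: pd.DataFrame) -> PedigreeResult:
    cats = assignments["category"]
    n_triads = int((cats == CATEGORY_TRIAD).sum())
    n_dyads = int(cats.isin([CATEGORY_DYAD_DAM, CATEGORY_DYAD_SIRE]).sum())
    n_un = int((cats == CATEGORY_NONE).sum())
    dams = set(assignments["dam_id"].dropna())
    sires = set(assignments["sire_id"].dropna())
    ratio = len(dams) / len(sires) if sires else float("nan")
    return PedigreeResult(
        assignments=assignments,
        n_s=len(assignments),
        n_triads=n_triads,
        n_dyads=n_dyads,
        n_unassigned=n_un,
        breeders=dams | sires,
        dam_sire_ratio=ratio,
        distinct_dams=len(dams),
        distinct_sires=len(sires),
    )


def pedigree_from_assignments(assignments: pd.DataFrame) -> PedigreeResult:
    """Summarize an externally supplied assignment table (e.g. ground truth)."""
    df = assignments.copy()
    if "category" not in df.columns:
        def cat(row):
            if pd.notna(row.get("dam_id")) and pd.notna(row.get("sire_id")):
                return CATEGORY_TRIAD
            if pd.notna(row.get("dam_id")):
                return CATEGORY_DYAD_DAM
            if pd.notna(row.get("sire_id")):
                return CATEGORY_DYAD_SIRE
            return CATEGORY_NONE
        df["category"] = df.apply(cat, axis=1)
    if "log_odds" not in df.columns:
        df["log_odds"] = np.nan
    if "ambiguous" not in df.columns:
        df["ambiguous"] = False
    return _summarize(df)


class ParentageModel:
    """statsmodels-flavoured front end: model holds the data, fit() assigns.

    Parameters
    ----------
    individuals
        Identified individuals with consensus genotypes and sexes.
    freqs
        Optional reference-allele frequencies; plug-in estimates from the
        individuals otherwise.
    """

    def __init__(self, individuals: IndividualTable, freqs: np.ndarray | None = None):
        self.individuals = individuals
        self.freqs = freqs

    def fit(self, config: ParentageConfig | None = None, **kwargs) -> PedigreeResult:
        cfg = config or ParentageConfig(**kwargs)
        return reconstruct_pedigree(self.individuals, self.freqs, cfg)
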