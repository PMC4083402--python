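"""Call annotation and cohort-level analytics.

Annotation attaches locus labels, homopolymer/tandem-repeat membership,
HmtDB-style per-position variability (low-variability flag at < 0.20) and
external pathogenicity predictions (MutPred score >= 0.70 or a "disease"
class counts as damaging) to per-sample call tables.  Cohort analytics build
the sample x 11-HF-class count matrix, cluster it hierarchically (Euclidean,
complete linkage), and compare sample groups with Welch t-tests and Fisher
exact / Monte-Carlo tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .calling import HF_CLASS_LABELS, classify_hf
from .reference import (
    HomopolymerRun,
    LocusAnnotation,
    in_homopolymer,
    intergenic_length,
    locus_of,
)

log = logging.getLogger(__name__)

LOW_VARIABILITY_CUTOFF = 0.20  # strict: variability < 0.20
MUTPRED_DAMAGING = 0.70  # inclusive: score >= 0.70
EBV_LCL_CUTOFF = 400  # strict: coverage > 400 marks an LCL


# ----------------------------------------------------------------------
# annotation


def load_variability(source) -> dict[int, float]:
    """TSV ``position  variability`` (header optional); values must be in [0,1]."""
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    out: dict[int, float] = {}
    try:
        for ln in handle:
            parts = ln.strip().split("\t")
            if not parts or not parts[0] or not parts[0][0].isdigit():
                continue
            pos, val = int(parts[0]), float(parts[1])
            if not 0 <= val <= 1:
                raise ValueError(f"variability at {pos} outside [0,1]: {val}")
            out[pos] = val
    finally:
        if close:
            handle.close()
    return out


def load_repeat_intervals(source) -> list[tuple[int, int]]:
    """BED intervals (0-based half-open) -> list of 1-based inclusive spans."""
    if isinstance(source, str):
        handle = open(source)
        close = True
    else:
        handle = source
        close = False
    spans = []
    try:
        for ln in handle:
            if not ln.strip() or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            spans.append((int(parts[1]) + 1, int(parts[2])))
    finally:
        if close:
            handle.close()
    return spans


def annotate_calls(
    calls: pd.DataFrame,
    loci: list[LocusAnnotation],
    homopolymers: list[HomopolymerRun],
    L: int,
    repeat_intervals: list[tuple[int, int]] | None = None,
    variability: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Attach locus / homopolymer / repeat / variability annotations.

    Insertions count as inside a homopolymer when the anchor or the position
    just after it lies within a run (an inserted base extending a run should
    count).  Variability missing for a position leaves the value absent and
    the low-variability flag unknown (NA).
    """
    df = calls.copy()

    def _locus(p):
        hits = locus_of(loci, int(p))
        return ",".join(hits) if hits else "intergenic"

    def _homopoly(row):
        p = int(row["pos"])
        if row["vtype"] == "insertion":
            return in_homopolymer(homopolymers, p, L) or in_homopolymer(
                homopolymers, p % L + 1, L
            )
        return in_homopolymer(homopolymers, p, L)

    def _repeat(p):
        if repeat_intervals is None:
            return False
        return any(s <= int(p) <= e for s, e in repeat_intervals)

    df["locus"] = df["pos"].map(_locus)
    df["in_homopolymer"] = df.apply(_homopoly, axis=1)
    df["in_repeat"] = df["pos"].map(_repeat)
    if variability is not None:
        df["variability"] = df["pos"].map(lambda p: variability.get(int(p), np.nan))
        df["low_variability"] = pd.array(
            [
                (v < LOW_VARIABILITY_CUTOFF) if not math.isnan(v) else pd.NA
                for v in df["variability"]
            ],
            dtype="boolean",
        )
    else:
        df["variability"] = np.nan
        df["low_variability"] = pd.array([pd.NA] * len(df), dtype="boolean")
    return df


def aggregate_pathogenicity(raw: pd.DataFrame) -> pd.DataFrame:
    """Combine per-variant predictor outputs into damaging_any / damaging_all.

    Expected columns: pos, ref, alt, mutpred_score (float or NA),
    polyphen_class, snpsgo_class (strings or NA).  MutPred is damaging at
    score >= 0.70 (inclusive); the classifiers at class == "disease"
    (case-insensitive).  ``damaging_any`` ORs over the tools present;
    ``damaging_all`` requires all three present and damaging.  Rows with a
    MutPred score outside [0,1] are rejected.
    """
    df = raw.copy()
    scores = pd.to_numeric(df.get("mutpred_score"), errors="coerce")
    bad = scores.notna() & ((scores < 0) | (scores > 1))
    if bad.any():
        log.warning("rejecting %d pathogenicity rows with score outside [0,1]", bad.sum())
        df = df[~bad].copy()
        scores = scores[~bad]

    def _class_damaging(col):
        vals = df.get(col)
        if vals is None:
            return pd.Series([pd.NA] * len(df), index=df.index, dtype="boolean")
        return pd.array(
            [
                (str(v).strip().lower() == "disease") if pd.notna(v) and str(v).strip() else pd.NA
                for v in vals
            ],
            dtype="boolean",
        )

    mp = pd.array(
        [(s >= MUTPRED_DAMAGING) if pd.notna(s) else pd.NA for s in scores],
        dtype="boolean",
    )
    pp = _class_damaging("polyphen_class")
    sg = _class_damaging("snpsgo_class")
    tools = pd.DataFrame({"mutpred": mp, "polyphen": pp, "snpsgo": sg}, index=df.index)
    if tools.isna().all(axis=1).any():
        raise ValueError("pathogenicity rows must carry at least one tool prediction")
    df["mutpred_damaging"] = mp
    df["polyphen_damaging"] = pp
    df["snpsgo_damaging"] = sg
    df["damaging_any"] = tools.fillna(False).any(axis=1)
    df["damaging_all"] = tools.notna().all(axis=1) & tools.fillna(False).all(axis=1)
    return df


def sharedness(
    cohort_calls: pd.DataFrame, populations: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-variant carrier counts across a multi-sample call table.

    Keyed by (pos, ref, alt, vtype); ``shared`` is False for private variants
    (exactly one carrying sample).  With a ``sample -> population`` metadata
    table, the number of carrying populations is added.
    """
    if cohort_calls.empty:
        return pd.DataFrame(
            columns=["pos", "ref", "alt", "vtype", "n_samples", "n_populations", "shared"]
        )
    df = cohort_calls.copy()
    if populations is not None:
        pop_map = populations.set_index("sample")["population"]
        df["population"] = df["sample"].map(pop_map)
    grouped = df.groupby(["pos", "ref", "alt", "vtype"], sort=True)
    out = grouped.agg(n_samples=("sample", "nunique")).reset_index()
    if populations is not None:
        out = out.merge(
            grouped.agg(n_populations=("population", "nunique")).reset_index(),
            on=["pos", "ref", "alt", "vtype"],
        )
    else:
        out["n_populations"] = pd.NA
    out["shared"] = out["n_samples"] > 1
    return out


def normalize_by_locus(
    calls: pd.DataFrame, loci: list[LocusAnnotation], L: int
) -> pd.DataFrame:
    """Per-locus variant counts and length-normalized rates.

    Split by zygosity and variant type; an ``intergenic`` bucket covers
    positions outside every locus (its length is the uncovered residue of the
    circle).  Wrapped loci use the wrap-aware length.
    """
    for lc in loci:
        if lc.length(L) < 1:
            raise ValueError(f"locus {lc.locus} has non-positive length")
    rows = []
    cats = [(z, v) for z in ("homoplasmic", "heteroplasmic") for v in ("mismatch", "insertion", "deletion")]
    buckets: list[tuple[str, int]] = [(lc.locus, lc.length(L)) for lc in loci]
    buckets.append(("intergenic", max(intergenic_length(loci, L), 1)))
    for name, length in buckets:
        if name == "intergenic":
            mask = calls["pos"].map(lambda p: not locus_of(loci, int(p))).astype(bool)
        else:
            lc = next(l for l in loci if l.locus == name)
            mask = calls["pos"].map(lambda p: lc.contains(int(p))).astype(bool)
        sub = calls[mask]
        for zyg, vt in cats:
            n = int(((sub["zygosity"] == zyg) & (sub["vtype"] == vt)).sum())
            rows.append(
                {
                    "locus": name,
                    "length": length,
                    "zygosity": zyg,
                    "vtype": vt,
                    "count": n,
                    "rate": n / length,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# sample source classification


@dataclass(frozen=True)
class SourceLabel:
    sample: str
    ebv_coverage: float
    label: str  # blood | LCL | unknown


def classify_source(ebv_table: pd.DataFrame) -> pd.DataFrame:
    """EBV coverage 0 -> blood; > 400 -> LCL; in between -> unknown."""
    df = ebv_table.copy()
    cov = pd.to_numeric(df["ebv_coverage"])
    if (cov < 0).any():
        raise ValueError("negative EBV coverage")
    df["label"] = np.where(cov == 0, "blood", np.where(cov > EBV_LCL_CUTOFF, "LCL", "unknown"))
    return df


# ----------------------------------------------------------------------
# HF-class matrix and clustering


def build_hf_matrix(cohort_calls: pd.DataFrame) -> pd.DataFrame:
    """Sample x 11-HF-class count matrix (zero-filled, PASS calls only)."""
    df = cohort_calls
    if "filter_status" in df.columns:
        df = df[df["filter_status"] == "PASS"]
    samples = sorted(cohort_calls["sample"].unique())
    mat = pd.DataFrame(0, index=samples, columns=list(HF_CLASS_LABELS))
    for sample, sub in df.groupby("sample"):
        for hf in sub["hf"]:
            mat.loc[sample, classify_hf(float(hf))] += 1
    mat.index.name = "sample"
    return mat


@dataclass
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_newick: str
    col_newick: str


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return rec(tree, tree.dist) + ";"


def hier_cluster(matrix: pd.DataFrame, method: str = "complete") -> ClusterResult:
    """Agglomerative clustering of rows and columns (Euclidean distance).

    Deterministic: scipy's linkage breaks ties by index.  A single-row matrix
    returns the identity ordering with a warning.
    """
    rows = [str(r) for r in matrix.index]
    cols = [str(c) for c in matrix.columns]
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        log.warning("hier_cluster called with a single row; identity ordering")
        return ClusterResult(rows, cols, None, None, f"({','.join(rows)});", "")
    Zr = hierarchy.linkage(X, method=method, metric="euclidean")
    row_order = [rows[i] for i in hierarchy.leaves_list(Zr)]
    if X.shape[1] >= 2:
        Zc = hierarchy.linkage(X.T, method=method, metric="euclidean")
        col_order = [cols[i] for i in hierarchy.leaves_list(Zc)]
        col_newick = _linkage_to_newick(Zc, cols)
    else:
        Zc, col_order, col_newick = None, cols, ""
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=Zr,
        col_linkage=Zc,
        row_newick=_linkage_to_newick(Zr, rows),
        col_newick=col_newick,
    )


# ----------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class ComparisonResult:
    mode: str
    statistic: float | None
    pvalue: float
    n_replicates: int | None = None


def _table_logpmf(table: np.ndarray) -> float:
    """Log-probability of an r x c table under fixed margins (hypergeometric)."""
    table = np.asarray(table, dtype=np.int64)
    rs, cs = table.sum(axis=1), table.sum(axis=0)
    n = table.sum()
    lg = math.lgamma
    return (
        sum(lg(r + 1) for r in rs)
        + sum(lg(c + 1) for c in cs)
        - lg(n + 1)
        - sum(lg(x + 1) for x in table.ravel())
    )


def group_compare(
    group_a,
    group_b=None,
    mode: str = "t_two_tailed",
    seed: int | None = None,
    n_replicates: int = 100_000,
) -> ComparisonResult:
    """Compare two sample groups or a contingency table.

    Modes: ``t_two_tailed`` / ``t_one_tailed`` — Welch (unequal-variance)
    t-test on per-sample counts, the one-tailed form testing mean(A) >
    mean(B); ``fisher_2x2`` — exact two-sided Fisher; ``fisher_rxc_montecarlo``
    — seeded Monte-Carlo permutation over tables with the observed margins
    (group_a is the table; group_b ignored).
    """
    if mode in ("t_two_tailed", "t_one_tailed"):
        a = np.asarray(group_a, dtype=float)
        b = np.asarray(group_b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test requires at least 2 observations per group")
        alternative = "greater" if mode == "t_one_tailed" else "two-sided"
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
        return ComparisonResult(mode, float(res.statistic), float(res.pvalue))
    if mode == "fisher_2x2":
        table = np.asarray(group_a, dtype=np.int64)
        if table.shape != (2, 2):
            raise ValueError("fisher_2x2 needs a 2x2 table")
        if (table < 0).any():
            raise ValueError("negative cell in contingency table")
        _odds, p = stats.fisher_exact(table, alternative="two-sided")
        return ComparisonResult(mode, float(_odds), float(p))
    if mode == "fisher_rxc_montecarlo":
        table = np.asarray(group_a, dtype=np.int64)
        if (table < 0).any():
            raise ValueError("negative cell in contingency table")
        rng = np.random.default_rng(seed)
        obs = _table_logpmf(table)
        sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
        samples = sampler.rvs(n_replicates, random_state=rng)
        extreme = sum(
            1 for t in samples if _table_logpmf(t) <= obs + 1e-9
        )
        p = (extreme + 1) / (n_replicates + 1)
        return ComparisonResult(mode, None, float(p), n_replicates)
    raise ValueError(f"unknown mode {mode!r}")
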