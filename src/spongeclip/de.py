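"""Count-based differential expression for sponge vs. control libraries.

A deliberately small DE engine for the sponge contrast: genes are filtered
on counts-per-million (cpm > 10 in more than two samples), libraries are
normalized by trimmed-mean-of-M (TMM) factors, and per-gene differential
expression is tested with a moderated two-sample t statistic on log2-cpm
with an empirical-Bayes pooled variance (prior df and prior variance
estimated by moment matching on the distribution of log sample variances).
Strict calls use |fold-change| > 1.5 at FDR < 0.1; the relaxed up-regulated
set uses log2FC > 0.3 with no FDR condition, reflecting the typically mild
effect of miRNA withdrawal on target mRNA abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrich import bh_adjust, hypergeom_upper

CONDITIONS = ("target_sponge", "control_sponge", "other_sponge")


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class DEConfig:
    cpm_cutoff: float = 10.0
    cpm_min_samples: int = 2  # "more than" this many samples
    fc_cutoff: float = 1.5
    fdr_cutoff: float = 0.1
    relaxed_log2fc: float = 0.3
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cpm_cutoff", "fc_cutoff", "fdr_cutoff", "relaxed_log2fc", "prior_count"):
            if getattr(self, name) <= 0:
                raise DEError(f"{name} must be positive")


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads (raw library sizes by default)."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise DEError("zero library size")
    return counts.div(lib_sizes, axis=1) * 1e6


def cpm_filter(counts: pd.DataFrame, cfg: DEConfig) -> pd.Index:
    """Genes with cpm > cutoff in strictly more than ``cpm_min_samples`` samples."""
    keep = (cpm(counts) > cfg.cpm_cutoff).sum(axis=1) > cfg.cpm_min_samples
    return counts.index[keep]


# ---------------------------------------------------------------------------
# TMM normalization


def _choose_reference(counts: pd.DataFrame) -> int:
    """Sample whose upper-quartile cpm is closest to the mean upper quartile."""
    uq = cpm(counts).quantile(0.75, axis=0).to_numpy()
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    counts: pd.DataFrame,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
    ref_column: int | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M normalization factors (geometric mean 1).

    For each sample the factor is 2^(trimmed mean of M), where M is the
    per-gene log2 ratio of cpm vs. the reference sample, trimming the most
    extreme 30% of M values and 5% of A values on each side (unweighted).
    Multiplying a library size by its factor gives the effective size.
    """
    arr = counts.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if (lib <= 0).any():
        raise DEError("zero library size")
    if arr.shape[0] <= 1:
        warnings.warn("TMM on a degenerate (<=1 gene) matrix; factors set to 1")
        return pd.Series(1.0, index=counts.columns)
    if ref_column is None:
        ref_column = _choose_reference(counts)
    ref = arr[:, ref_column] / lib[ref_column]
    factors = np.ones(arr.shape[1])
    for j in range(arr.shape[1]):
        if j == ref_column:
            continue
        obs = arr[:, j] / lib[j]
        ok = (obs > 0) & (ref > 0)
        if ok.sum() == 0:
            continue
        m = np.log2(obs[ok] / ref[ok])
        a = 0.5 * np.log2(obs[ok] * ref[ok])
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_l = np.floor(n * log_ratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * abs_expr_trim) + 1
        hi_s = n + 1 - lo_s
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if keep.sum() == 0:
            continue
        factors[j] = 2.0 ** np.mean(m[keep])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


# ---------------------------------------------------------------------------
# Moderated t


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise DEError("trigamma_inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes moderated variances (moment matching on log s²).

    Returns (moderated variances, prior df d0, prior variance s0²); d0 may
    be ``inf`` when the observed variance spread is no wider than sampling
    noise alone.
    """
    pos = s2 > 0
    if pos.sum() < 2:
        return s2, 0.0, float(np.mean(s2[pos])) if pos.any() else 0.0
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s0 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0 = float(np.exp(e_mean))
        s2_post = np.full_like(s2, s0)
    return s2_post, d0, s0


def de_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    cfg: DEConfig,
    contrast: tuple[str, str] = ("target_sponge", "control_sponge"),
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression for one contrast.

    ``samples`` must have the sample ids as index and a ``condition``
    column; ``contrast`` is (numerator, denominator), so a positive log2fc
    means higher in the first condition.  Genes should already be
    cpm-filtered.  Returns a DataFrame indexed by gene with columns
    log2fc, t, df, p, fdr.
    """
    num, den = contrast
    s_num = samples.index[samples["condition"] == num]
    s_den = samples.index[samples["condition"] == den]
    if len(s_num) < 2 or len(s_den) < 2:
        raise DEError(
            f"need >=2 replicates per condition, got {len(s_num)} {num} / {len(s_den)} {den}"
        )
    sub = counts[list(s_num) + list(s_den)]
    factors = tmm_factors(sub)
    eff_lib = sub.sum(axis=0) * factors
    logcpm = np.log2((sub + cfg.prior_count).div(eff_lib, axis=1) * 1e6)

    x1 = logcpm[list(s_num)].to_numpy()
    x2 = logcpm[list(s_den)].to_numpy()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    lfc = m1 - m2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df_resid = n1 + n2 - 2
    s2 = ss / df_resid
    s2_post, d0, _s0 = _squeeze_var(s2, df_resid)
    df_total = df_resid + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    res = pd.DataFrame(
        {
            "log2fc": lfc,
            "t": t,
            "df": df_total,
            "p": p,
            "fdr": bh_adjust(p),
        },
        index=sub.index,
    )
    res.index.name = "gene_id"
    return res


def call_de(results: pd.DataFrame, cfg: DEConfig) -> dict[str, set[str]]:
    """Strict up/down calls (|FC| > cutoff, FDR < cutoff) and the relaxed up set."""
    lfc_cut = np.log2(cfg.fc_cutoff)
    up_strict = set(
        results.index[(results["log2fc"] > lfc_cut) & (results["fdr"] < cfg.fdr_cutoff)]
    )
    down_strict = set(
        results.index[(results["log2fc"] < -lfc_cut) & (results["fdr"] < cfg.fdr_cutoff)]
    )
    up_relaxed = set(results.index[results["log2fc"] > cfg.relaxed_log2fc])
    return {"up_strict": up_strict, "down_strict": down_strict, "up_relaxed": up_relaxed}


def specificity_screen(
    calls_target: dict[str, set[str]],
    calls_other: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric overlap between the strict DE sets of two sponges.

    Small overlap p-values would indicate that the two sponges perturb the
    same genes; a non-targeting (or unrelated) sponge is expected to show
    no significant overlap.
    """
    rows = []
    for direction in ("up_strict", "down_strict"):
        a = calls_target[direction] & universe
        b = calls_other[direction] & universe
        k = len(a & b)
        p = hypergeom_upper(len(universe), len(a), len(b), k) if universe else 1.0
        rows.append(
            {"direction": direction, "n_target": len(a), "n_other": len(b), "overlap": k, "p": p}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def load_counts(counts_path, samples_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts TSV (gene × sample, first column gene id) + sample sheet TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    if "condition" not in samples.columns:
        raise DEError("sample sheet needs a 'condition' column")
    if (counts.to_numpy() < 0).any():
        raise DEError("count matrix has negative entries")
    missing = [s for s in samples.index if s not in counts.columns]
    if missing:
        raise DEError(f"samples missing from count matrix: {missing}")
    return counts, samples
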