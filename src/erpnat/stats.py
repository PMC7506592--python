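"""Inferential layer: normality gating, Wilcoxon signed-rank, paired t,
2×2 within-subjects ANOVA with partial η², Bonferroni-corrected post hocs.

The Wilcoxon variant matches classic statistical-package behaviour: zero
differences dropped, tied magnitudes mid-ranked, tie-corrected normal
approximation without continuity correction; for n ≤ 12 effective pairs the
exact sign-permutation distribution is used instead. The 2×2 repeated-
measures ANOVA treats subject as a random blocking factor and tests each
effect against its own effect×subject error term, so each F has df (1, n−1)
and equals the squared paired t on that effect's contrast scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .exceptions import ConfigurationError

ETA_SQ_CUTOFFS = (("large", 0.14), ("medium", 0.06), ("small", 0.01))


@dataclass(frozen=True)
class PairedSample:
    """Within-subject paired values with condition labels."""

    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        keep = np.isfinite(a) & np.isfinite(b)
        object.__setattr__(self, "values_a", a[keep])
        object.__setattr__(self, "values_b", b[keep])
        if self.values_a.size != self.values_b.size:
            raise ConfigurationError("paired samples must have equal length")
        if self.values_a.size < 2:
            raise ConfigurationError("need ≥2 complete pairs")

    @property
    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b

    @property
    def n(self) -> int:
        return int(self.values_a.size)


@dataclass(frozen=True)
class WilcoxonResult:
    Z: float
    p: float
    mean_rank_pos: float        # mean rank of pairs with a > b
    mean_rank_neg: float        # mean rank of pairs with a < b
    n_effective: int
    method: str                 # 'exact' | 'approx'
    W_pos: float


@dataclass(frozen=True)
class EffectResult:
    F: float
    df: tuple[int, int]
    p: float
    eta_p_sq: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class RmAnovaResult:
    effects: dict                      # name → EffectResult
    cell_means: pd.DataFrame           # index levels of factor a, columns b
    cell_ses: pd.DataFrame
    n_subjects: int
    factors: tuple[str, str]


@dataclass(frozen=True)
class PosthocContrast:
    name: str
    mean_diff: float
    t: float
    df: int
    p: float
    alpha_bonf: float
    significant: bool


@dataclass(frozen=True)
class PosthocResult:
    contrasts: list = field(default_factory=list)
    alpha: float = 0.05

    @property
    def alpha_bonf(self) -> float:
        return self.contrasts[0].alpha_bonf if self.contrasts else np.nan


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------

def shapiro_wilk(sample: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p (normality gate; valid for 3 ≤ n ≤ 2000)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 2000:
        raise ConfigurationError(f"Shapiro–Wilk needs 3 ≤ n ≤ 2000, got {x.size}")
    if np.ptp(x) == 0:
        raise ConfigurationError("Shapiro–Wilk undefined for a constant sample")
    w, p = sstats.shapiro(x)
    return float(w), float(p)


def paired_t(pairs: PairedSample) -> tuple[float, int, float]:
    """Two-sided paired t: t = mean(d)/(sd(d)/√n), df = n−1."""
    d = pairs.differences
    n = pairs.n
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        raise ConfigurationError("zero variance of nonzero differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nz = d[d != 0]
    ranks = sstats.rankdata(np.abs(nz))       # mid-ranks for ties
    return nz, ranks


def _exact_two_sided_p(ranks: np.ndarray, w_pos: float) -> float:
    """P(|W − μ| ≥ |w − μ|) over all 2^n sign assignments, by convolution.

    Ranks are half-integers at worst; doubling makes them integers so the
    distribution of 2W is a polynomial convolution.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:dist.size - r]
        dist = 0.5 * (dist + shifted)
    mu = total / 2.0
    dev = abs(2 * w_pos - mu)
    support = np.arange(total + 1)
    return float(dist[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(pairs: PairedSample,
                         method: str = "auto") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences (two-sided).

    ``method='auto'`` uses exact sign-permutation enumeration for ≤12
    effective pairs and the tie-corrected normal approximation (no
    continuity correction) otherwise. Z is signed by ``W_pos − E[W]``, so a
    predominance of negative differences (a < b) yields a negative Z.
    """
    if method not in ("auto", "exact", "approx"):
        raise ConfigurationError(f"unknown wilcoxon method {method!r}")
    d = pairs.differences
    nz, ranks = _signed_ranks(d)
    n_eff = nz.size
    if n_eff < 1:
        raise ConfigurationError("all differences are zero: no information")
    w_pos = float(ranks[nz > 0].sum())
    mean_rank_pos = float(ranks[nz > 0].mean()) if (nz > 0).any() else np.nan
    mean_rank_neg = float(ranks[nz < 0].mean()) if (nz < 0).any() else np.nan

    mu = n_eff * (n_eff + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var = (n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0
           - (tie_counts ** 3 - tie_counts).sum() / 48.0)
    z = 0.0 if var == 0 else (w_pos - mu) / np.sqrt(var)

    use_exact = method == "exact" or (method == "auto" and n_eff <= 12)
    if use_exact:
        p = _exact_two_sided_p(ranks, w_pos)
        how = "exact"
    else:
        p = min(2.0 * sstats.norm.sf(abs(z)), 1.0)
        how = "approx"
    return WilcoxonResult(Z=float(z), p=float(p),
                          mean_rank_pos=mean_rank_pos,
                          mean_rank_neg=mean_rank_neg,
                          n_effective=n_eff, method=how, W_pos=w_pos)


# ---------------------------------------------------------------------------
# 2×2 repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _pivot_2x2(table: pd.DataFrame, dv: str, subject: str,
               factors: tuple[str, str]) -> tuple[np.ndarray, list, list, list]:
    fa, fb = factors
    wide = table.pivot_table(index=subject, columns=[fa, fb], values=dv,
                             aggfunc="mean")
    a_levels = sorted(table[fa].unique())
    b_levels = sorted(table[fb].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise ConfigurationError("rm_anova_2x2 needs exactly 2×2 factor levels")
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ConfigurationError(
            f"incomplete 2×2 cells for subjects: {incomplete}")
    cube = np.empty((wide.shape[0], 2, 2))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            cube[:, i, j] = wide[(a, b)].to_numpy()
    return cube, list(wide.index), a_levels, b_levels


def rm_anova_2x2(table: pd.DataFrame, dv: str = "amplitude_uv",
                 subject: str = "subject",
                 factors: tuple[str, str] = ("identity", "site"),
                 effect_names: tuple[str, str, str] = ("identity_type",
                                                       "modality",
                                                       "interaction"),
                 ) -> RmAnovaResult:
    """Two-way fully-within 2×2 ANOVA with partial η² per effect.

    Each effect is tested against its own effect×subject interaction, the
    univariate within-subjects decomposition; with two levels per factor
    sphericity is moot. ``effect_names`` maps (factor a, factor b,
    interaction) onto report keys.
    """
    cube, subjects, a_levels, b_levels = _pivot_2x2(table, dv, subject, factors)
    n = cube.shape[0]
    if n < 2:
        raise ConfigurationError("need ≥2 subjects")
    gm = cube.mean()
    m_a = cube.mean(axis=(0, 2))          # per level of factor a
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)              # 2×2 cell means
    m_s = cube.mean(axis=(1, 2))          # per subject
    m_as = cube.mean(axis=2)              # subject × a
    m_bs = cube.mean(axis=1)              # subject × b

    total_ss = float(((cube - gm) ** 2).sum())
    degenerate_tol = 1e-10 * max(1.0, total_ss)

    def effect(ss_effect: float, ss_error: float) -> EffectResult:
        df1, df2 = 1, n - 1
        if ss_effect < degenerate_tol and ss_error < degenerate_tol:
            # effect and its error term both numerically zero (e.g. exactly
            # additive data): report a null effect rather than 0/0 noise
            return EffectResult(F=0.0, df=(df1, df2), p=1.0, eta_p_sq=0.0,
                                ss_effect=0.0, ss_error=0.0)
        ms_e, ms_err = ss_effect / df1, ss_error / df2
        f = 0.0 if ms_err == 0 else ms_e / ms_err
        p = float(sstats.f.sf(f, df1, df2))
        eta = ss_effect / (ss_effect + ss_error) if ss_effect + ss_error > 0 else 0.0
        return EffectResult(F=float(f), df=(df1, df2), p=p,
                            eta_p_sq=float(eta), ss_effect=float(ss_effect),
                            ss_error=float(ss_error))

    ss_a = 2 * n * ((m_a - gm) ** 2).sum()
    ss_as = 2 * ((m_as - m_a[None, :] - m_s[:, None] + gm) ** 2).sum()
    ss_b = 2 * n * ((m_b - gm) ** 2).sum()
    ss_bs = 2 * ((m_bs - m_b[None, :] - m_s[:, None] + gm) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    fitted = (m_ab[None, :, :] + m_as[:, :, None] + m_bs[:, None, :]
              - m_a[None, :, None] - m_b[None, None, :] - m_s[:, None, None]
              + gm)
    ss_abs = ((cube - fitted) ** 2).sum()

    effects = {
        effect_names[0]: effect(ss_a, ss_as),
        effect_names[1]: effect(ss_b, ss_bs),
        effect_names[2]: effect(ss_ab, ss_abs),
    }
    cell_means = pd.DataFrame(m_ab, index=a_levels, columns=b_levels)
    cell_ses = pd.DataFrame(cube.std(axis=0, ddof=1) / np.sqrt(n),
                            index=a_levels, columns=b_levels)
    return RmAnovaResult(effects=effects, cell_means=cell_means,
                         cell_ses=cell_ses, n_subjects=n,
                         factors=factors)


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """η²p from an F ratio: F·df1 / (F·df1 + df2)."""
    if F < 0:
        raise ConfigurationError("F must be nonnegative")
    if df1 < 1 or df2 < 1:
        raise ConfigurationError("degrees of freedom must be ≥1")
    return float(F * df1 / (F * df1 + df2))


def effect_size_label(eta_p_sq: float) -> str:
    """Cutoff label: ≥0.14 large, ≥0.06 medium, ≥0.01 small, else negligible."""
    if not 0.0 <= eta_p_sq <= 1.0:
        raise ConfigurationError("η²p must be in [0,1]")
    for label, cutoff in ETA_SQ_CUTOFFS:
        if eta_p_sq >= cutoff:
            return label
    return "negligible"


# ---------------------------------------------------------------------------
# Planned post hocs
# ---------------------------------------------------------------------------

def _default_contrasts(factors: tuple[str, str],
                       a_levels: list, b_levels: list) -> list[tuple]:
    """The four simple effects of a 2×2: each factor within each level of
    the other."""
    fa, fb = factors
    out = []
    for b in b_levels:
        out.append((f"{fa} at {fb}={b}", {fb: b}, fa, a_levels))
    for a in a_levels:
        out.append((f"{fb} at {fa}={a}", {fa: a}, fb, b_levels))
    return out


def bonferroni_posthoc(table: pd.DataFrame, contrasts: list | None = None,
                       alpha: float = 0.05, dv: str = "amplitude_uv",
                       subject: str = "subject",
                       factors: tuple[str, str] = ("identity", "site"),
                       ) -> PosthocResult:
    """Planned paired-t simple-effect contrasts, Bonferroni-criterion flagged.

    The default contrast set is the four simple effects of the 2×2 design,
    giving the α/4 criterion (0.0125 at α = 0.05). A contrast is a tuple
    ``(name, {fixed_factor: level}, varied_factor, [level_hi, level_lo])``.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0,1)")
    cube, subjects, a_levels, b_levels = _pivot_2x2(table, dv, subject, factors)
    if contrasts is None:
        contrasts = _default_contrasts(factors, a_levels, b_levels)
    if not contrasts:
        raise ConfigurationError("empty contrast list")
    alpha_bonf = alpha / len(contrasts)

    wide = table.pivot_table(index=subject, columns=list(factors), values=dv,
                             aggfunc="mean")
    results = []
    for name, fixed, varied, levels in contrasts:
        (fixed_factor, fixed_level), = fixed.items()
        hi, lo = levels[0], levels[1]

        def cell(level):
            key = ((level, fixed_level) if varied == factors[0]
                   else (fixed_level, level))
            return wide[key].to_numpy()

        pair = PairedSample(cell(hi), cell(lo), str(hi), str(lo))
        t, df, p = paired_t(pair)
        results.append(PosthocContrast(
            name=name, mean_diff=float(pair.differences.mean()), t=t, df=df,
            p=p, alpha_bonf=alpha_bonf, significant=bool(p < alpha_bonf)))
    return PosthocResult(contrasts=results, alpha=alpha)
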