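"""Per-window population-genetic statistics for a four-taxon quartet.

Implements the frequency-based ABBA-BABA D statistic, the windowed
admixture-proportion estimator f_d, absolute divergence d_xy, and the
Weir & Cockerham (1984) F_ST estimator, together with the valid-SNP
count and depth summaries that the candidate-filter cascade consumes.

With derived-allele frequencies p̂_ij for populations (P1, P2, P3, O),
the per-site ABBA and BABA weights are

    ABBA_i = (1 − p̂_i1) p̂_i2 p̂_i3 (1 − p̂_i4)
    BABA_i = p̂_i1 (1 − p̂_i2) p̂_i3 (1 − p̂_i4)

and D = Σ(ABBA_i − BABA_i) / Σ(ABBA_i + BABA_i). f_d divides the same
numerator by its value when the donor frequency (the larger of p̂_2,
p̂_3, chosen per site) replaces both P2 and P3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, QuartetSpec

_ROLE_ORDER = ("P1", "P2", "P3", "O")


@dataclass
class SiteFrequencies:
    """Derived-allele frequencies per site for the four quartet populations.

    ``freqs[:, j]`` is p̂ for role j in (P1, P2, P3, O); NaN where the
    population has no called allele at the site. ``valid`` marks sites
    with all four frequencies defined (after polarization).
    """

    pos: np.ndarray                 # (n,) site positions
    freqs: np.ndarray               # (n, 4) float, NaN = undefined
    n_called: np.ndarray            # (n, 4) called allele counts
    derived_is_alt: np.ndarray      # (n,) bool

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.freqs).any(axis=1)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def __post_init__(self):
        f = self.freqs[np.isfinite(self.freqs)]
        if f.size and (f.min() < -1e-12 or f.max() > 1 + 1e-12):
            raise ValueError("frequencies must lie in [0, 1]")


def _pop_alt_frequency(dosages: np.ndarray, cols: np.ndarray):
    """Alternate-allele frequency over non-missing calls, with allele counts."""
    sub = dosages[:, cols]
    called = sub != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq, n_alleles


def site_frequencies(matrix: GenotypeMatrix, quartet: QuartetSpec,
                     site_idx: np.ndarray | None = None,
                     polarization: str = "outgroup-major") -> SiteFrequencies:
    """Polarize sites and compute per-population derived-allele frequencies.

    Under the default ``"outgroup-major"`` rule the ancestral allele is
    the majority allele in the outgroup; sites where the outgroup is at
    exactly 0.5 (e.g. a single heterozygous diploid) are excluded.
    ``"ref-ancestral"`` keeps such sites, treating the reference allele
    as ancestral everywhere.
    """
    if polarization not in ("outgroup-major", "ref-ancestral"):
        raise ValueError(f"unknown polarization rule {polarization!r}")
    if site_idx is None:
        site_idx = np.arange(matrix.n_sites)
    dos = matrix.dosages[site_idx]
    pos = matrix.pos[site_idx]
    idx = quartet.indices(matrix.samples)

    alt_freq = np.empty((len(site_idx), 4))
    n_called = np.empty((len(site_idx), 4), dtype=np.int64)
    for j, role in enumerate(_ROLE_ORDER):
        alt_freq[:, j], n_called[:, j] = _pop_alt_frequency(dos, idx[role])

    o_freq = alt_freq[:, 3]
    if polarization == "outgroup-major":
        keep = ~np.isclose(o_freq, 0.5) | np.isnan(o_freq)
        derived_is_alt = ~(o_freq > 0.5)
    else:
        keep = np.ones(len(site_idx), dtype=bool)
        derived_is_alt = np.ones(len(site_idx), dtype=bool)
    freqs = np.where(derived_is_alt[:, None], alt_freq, 1.0 - alt_freq)
    return SiteFrequencies(pos=pos[keep], freqs=freqs[keep],
                           n_called=n_called[keep],
                           derived_is_alt=derived_is_alt[keep])


# ---------------------------------------------------------------------------
# D and f_d
# ---------------------------------------------------------------------------

def abba_baba_components(freqs: SiteFrequencies):
    """Per-site (numerator, denominator) contributions to D over valid sites.

    Returns ``(num, den, pos)`` where num = ABBA − BABA and
    den = ABBA + BABA, restricted to sites with all four frequencies
    defined.
    """
    v = freqs.valid
    p1, p2, p3, p4 = (freqs.freqs[v, j] for j in range(4))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    return abba - baba, abba + baba, freqs.pos[v]


def d_statistic(freqs: SiteFrequencies) -> float:
    """Patterson's D from derived-allele frequencies; NaN when undefined."""
    num, den, _ = abba_baba_components(freqs)
    total = den.sum()
    if len(num) == 0 or total == 0:
        return float("nan")
    return float(num.sum() / total)


def f_d_components(freqs: SiteFrequencies):
    """Per-site (numerator, donor-denominator) contributions to f_d.

    The denominator is the D numerator evaluated with the per-site donor
    frequency P_D = max(p̂_2, p̂_3) substituted for both P2 and P3:
    S(P1, P_D, P_D, O)_i = p_D (1 − p̂_4) (p_D − p̂_1).
    """
    v = freqs.valid
    p1, p2, p3, p4 = (freqs.freqs[v, j] for j in range(4))
    num = (1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)
    pd = np.maximum(p2, p3)
    den = pd * (1 - p4) * (pd - p1)
    return num, den, freqs.pos[v]


def f_d_statistic(freqs: SiteFrequencies) -> float:
    """Windowed admixture-proportion estimator f_d.

    Reported as NaN when the window's D is not positive (the statistic is
    meaningful only for an excess of ABBA sharing) or the donor
    denominator is zero.
    """
    if not (d_statistic(freqs) > 0):
        return float("nan")
    num, den, _ = f_d_components(freqs)
    total = den.sum()
    if len(num) == 0 or total == 0:
        return float("nan")
    return float(num.sum() / total)


# ---------------------------------------------------------------------------
# d_xy
# ---------------------------------------------------------------------------

_PAIR_COLS = {"P1": 0, "P2": 1, "P3": 2, "O": 3}


def dxy_site_terms(freqs: SiteFrequencies, x: str, y: str):
    """Per-site d_xy contributions p_x(1−p_y) + p_y(1−p_x) with positions.

    Uses every site where both populations have a defined frequency
    (d_xy is symmetric in the allele labelling, so polarization is
    immaterial).
    """
    px = freqs.freqs[:, _PAIR_COLS[x]]
    py = freqs.freqs[:, _PAIR_COLS[y]]
    ok = ~np.isnan(px) & ~np.isnan(py)
    px, py = px[ok], py[ok]
    return px * (1 - py) + py * (1 - px), freqs.pos[ok]


def dxy(freqs: SiteFrequencies, x: str, y: str,
        normalization: int | str = "sites") -> float:
    """Mean pairwise divergence between populations ``x`` and ``y``.

    ``normalization="sites"`` (default) divides by the number of
    contributing SNP sites; passing an integer divides by that window
    length in bp instead.
    """
    terms, _ = dxy_site_terms(freqs, x, y)
    if len(terms) == 0:
        return float("nan")
    if normalization == "sites":
        n = len(terms)
    else:
        n = int(normalization)
        if n <= 0:
            raise ValueError("window-length normalization must be positive")
    return float(terms.sum() / n)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def fst_components(dosages: np.ndarray, cols_x: np.ndarray, cols_y: np.ndarray):
    """Per-site Weir & Cockerham (1984) variance components (a, b, c).

    Sites where either population has no called genotype, or where the
    pooled sample is monomorphic, contribute zeros.
    """
    r = 2
    comps = []
    for cols in (cols_x, cols_y):
        sub = dosages[:, cols]
        called = sub != MISSING
        n_i = called.sum(axis=1).astype(float)            # diploid individuals
        alt = np.where(called, sub, 0).sum(axis=1)
        het = np.where(called, sub == 1, False).sum(axis=1)
        comps.append((n_i, alt, het))
    n1, alt1, het1 = comps[0]
    n2, alt2, het2 = comps[1]

    usable = (n1 > 0) & (n2 > 0)
    a = np.zeros(dosages.shape[0])
    b = np.zeros(dosages.shape[0])
    c = np.zeros(dosages.shape[0])
    if not usable.any():
        return a, b, c

    n1u, n2u = n1[usable], n2[usable]
    p1 = alt1[usable] / (2 * n1u)
    p2 = alt2[usable] / (2 * n2u)
    h1 = het1[usable] / n1u
    h2 = het2[usable] / n2u

    nbar = (n1u + n2u) / r
    nc = (r * nbar - (n1u**2 + n2u**2) / (r * nbar)) / (r - 1)
    pbar = (n1u * p1 + n2u * p2) / (r * nbar)
    s2 = (n1u * (p1 - pbar) ** 2 + n2u * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1u * h1 + n2u * h2) / (r * nbar)

    with np.errstate(invalid="ignore", divide="ignore"):
        a_u = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                   - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b_u = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                     - hbar * (2 * nbar - 1) / (4 * nbar))
    c_u = hbar / 2
    # monomorphic pooled sites and single-individual populations carry no signal
    poly = (pbar > 0) & (pbar < 1) & (nbar > 1) & np.isfinite(a_u) & np.isfinite(b_u)
    a_u = np.where(poly, a_u, 0.0)
    b_u = np.where(poly, b_u, 0.0)
    c_u = np.where(poly, c_u, 0.0)
    a[usable], b[usable], c[usable] = a_u, b_u, c_u
    return a, b, c


def fst_weir_cockerham(matrix: GenotypeMatrix, pop_x, pop_y,
                       site_idx: np.ndarray | None = None) -> float:
    """Windowed Weir & Cockerham F_ST as the ratio of summed components.

    ``pop_x``/``pop_y`` are sequences of sample ids. The weighted
    multi-site estimator Σa / Σ(a+b+c) is returned unclamped (small
    negative values are legitimate for the estimator); NaN when no
    polymorphic site is usable.
    """
    lookup = {s: i for i, s in enumerate(matrix.samples)}
    cols_x = np.array([lookup[s] for s in pop_x], dtype=int)
    cols_y = np.array([lookup[s] for s in pop_y], dtype=int)
    dos = matrix.dosages if site_idx is None else matrix.dosages[site_idx]
    a, b, c = fst_components(dos, cols_x, cols_y)
    denom = (a + b + c).sum()
    if denom == 0:
        return float("nan")
    return float(a.sum() / denom)


# ---------------------------------------------------------------------------
# Window bookkeeping
# ---------------------------------------------------------------------------

def valid_snp_count(freqs: SiteFrequencies) -> int:
    """Sites with defined frequencies in all four populations after polarization."""
    return int(freqs.valid.sum())


def window_depth_summary(matrix: GenotypeMatrix, quartet: QuartetSpec,
                         site_idx: np.ndarray) -> dict:
    """Mean per-genotype read depth over the window, per quartet taxon.

    NaN for a taxon with no DP calls in the window; all-NaN (with a
    warning) when the matrix carries no depth information at all.
    """
    out = {}
    if matrix.depths is None:
        warnings.warn("no DP field in genotype matrix; depth filter will be skipped")
        return {r: float("nan") for r in _ROLE_ORDER}
    idx = quartet.indices(matrix.samples)
    dp = matrix.depths[site_idx]
    for role in _ROLE_ORDER:
        sub = dp[:, idx[role]].astype(float)
        sub[sub == MISSING] = np.nan
        out[role] = float(np.nanmean(sub)) if np.isfinite(sub).any() else float("nan")
    return out
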