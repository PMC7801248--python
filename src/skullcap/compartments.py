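"""A/B chromatin compartments from a binned Hi-C contact matrix.

The standard eigenvector pipeline: per chromosome, observed/expected (O/E)
normalisation removes the distance-decay signal, the Pearson correlation
matrix of the O/E rows is formed, and the sign pattern of its leading
eigenvector (power iteration) segments bins into A (open, gene-dense) and B
(closed, TE-rich). The sign is oriented so that positive-eigenvector bins
have the higher mean gene density. Density contrasts between compartments
are tested by label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentProfile",
    "CompartmentStats",
    "ContactMatrix",
    "call_compartments",
    "compare_compartments",
    "oe_normalize",
    "power_iteration",
    "read_contact_matrix",
    "write_contact_matrix",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts; bins are (chromosome, start, end)."""

    bins: list[tuple[str, int, int]]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix must be symmetric")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be nonnegative")
        sizes = {e - s for _, s, e in self.bins}
        if len(sizes) > 1:
            raise ValueError(f"bin sizes not uniform: {sorted(sizes)}")

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c, _, _ in self.bins:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom: str) -> slice:
        idx = [i for i, (c, _, _) in enumerate(self.bins) if c == chrom]
        return slice(idx[0], idx[-1] + 1)


@dataclass
class CompartmentProfile:
    bins: list[tuple[str, int, int]]
    eigenvector: np.ndarray           # nan on masked bins
    calls: np.ndarray                 # 'A' / 'B' / 'masked'
    fraction_A: float
    low_signal: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [b[0] for b in self.bins],
            "start": [b[1] for b in self.bins],
            "end": [b[2] for b in self.bins],
            "eigenvector": self.eigenvector,
            "call": self.calls,
        })


@dataclass
class CompartmentStats:
    mean_te_A: float
    mean_te_B: float
    mean_gene_A: float
    mean_gene_B: float
    p_te: float
    p_gene: float


def oe_normalize(counts: np.ndarray) -> np.ndarray:
    """Observed/expected normalisation of one chromosome's square matrix.

    Expected is the mean observed count at each diagonal distance over
    unmasked bins; bins with zero row sum are masked (rows/columns nan).
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    mask = counts.sum(axis=1) > 0
    if not mask.any():
        raise ValueError("all bins masked (zero contacts)")
    oe = np.full_like(counts, np.nan)
    idx = np.nonzero(mask)[0]
    sub = counts[np.ix_(idx, idx)]
    d = np.abs(idx[:, None] - idx[None, :])
    ratio = np.ones_like(sub)
    for dist in np.unique(d):
        sel = d == dist
        m = sub[sel].mean()
        # distances with no observed contacts carry no signal: O/E neutral 1
        if m > 0:
            ratio[sel] = sub[sel] / m
    oe[np.ix_(idx, idx)] = ratio
    return oe


def power_iteration(matrix: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 10_000) -> tuple[float, np.ndarray]:
    """Leading (largest-magnitude) eigenpair of a symmetric matrix.

    Deterministic start vector; raises RuntimeError on non-convergence.
    """
    n = matrix.shape[0]
    v = np.linspace(1.0, 2.0, n)
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(max_iter):
        w = matrix @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0, v
        w /= norm
        if min(np.linalg.norm(w - v), np.linalg.norm(w + v)) < tol:
            lam = float(w @ matrix @ w)
            return lam, w
        v = w
    raise RuntimeError(f"power iteration did not converge in {max_iter} iterations")


def call_compartments(matrix: ContactMatrix, gene_density: np.ndarray,
                      low_signal_threshold: float = 0.05) -> CompartmentProfile:
    """Per-chromosome eigenvector compartment calls, A oriented gene-dense.

    Chromosomes with a single usable bin are masked entirely. A chromosome is
    flagged low-signal when the leading eigenvalue carries less than
    ``low_signal_threshold`` of the correlation matrix's total spectrum.
    """
    gene_density = np.asarray(gene_density, dtype=float)
    if len(gene_density) != len(matrix.bins):
        raise ValueError("gene_density not aligned to bins")
    n = len(matrix.bins)
    ev = np.full(n, np.nan)
    calls = np.array(["masked"] * n, dtype=object)
    low_signal: dict[str, bool] = {}
    for chrom in matrix.chromosomes:
        sl = matrix.chrom_slice(chrom)
        sub = matrix.counts[sl, sl]
        if sub.shape[0] < 2:
            continue
        try:
            oe = oe_normalize(sub)
        except ValueError:
            continue
        usable = ~np.isnan(oe).all(axis=1)
        # constant O/E rows have no correlation structure; mask them too
        with np.errstate(invalid="ignore"):
            stds = np.nanstd(oe, axis=1)
        usable &= stds > 0
        idx = np.nonzero(usable)[0]
        if len(idx) < 2:
            continue
        corr = np.corrcoef(oe[np.ix_(idx, idx)])
        try:
            lam, vec = power_iteration(corr)
        except RuntimeError as err:
            raise RuntimeError(f"{chrom}: {err}") from err
        # correlation matrices are PSD: sum(|eigenvalues|) = trace = len(idx)
        low_signal[chrom] = abs(lam) / len(idx) < low_signal_threshold
        gd = gene_density[sl][idx]
        pos = vec > 0
        if pos.any() and (~pos).any():
            if gd[pos].mean() < gd[~pos].mean():
                vec = -vec
        chrom_ev = np.full(sub.shape[0], np.nan)
        chrom_ev[idx] = vec
        ev[sl] = chrom_ev
        chrom_calls = np.array(["masked"] * sub.shape[0], dtype=object)
        chrom_calls[idx] = np.where(vec > 0, "A", "B")
        calls[sl] = chrom_calls
    unmasked = calls != "masked"
    if not unmasked.any():
        raise ValueError("no unmasked bins on any chromosome")
    fraction_a = float((calls[unmasked] == "A").mean())
    return CompartmentProfile(bins=matrix.bins, eigenvector=ev, calls=calls,
                              fraction_A=fraction_a, low_signal=low_signal)


def compare_compartments(profile: CompartmentProfile, te_density, gene_density,
                         n_perm: int = 10_000, seed: int = 0) -> CompartmentStats:
    """Two-sided permutation tests of A-vs-B mean density differences.

    p = (1 + #{|diff_perm| >= |diff_obs|}) / (1 + n_perm).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    te = np.asarray(te_density, dtype=float)
    gene = np.asarray(gene_density, dtype=float)
    keep = profile.calls != "masked"
    labels = profile.calls[keep] == "A"
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 bins in each compartment")
    te, gene = te[keep], gene[keep]
    rng = np.random.default_rng(seed)

    def perm_p(values: np.ndarray) -> tuple[float, float, float]:
        obs = values[labels].mean() - values[~labels].mean()
        count = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(labels)
            diff = values[shuffled].mean() - values[~shuffled].mean()
            if abs(diff) >= abs(obs):
                count += 1
        return values[labels].mean(), values[~labels].mean(), \
            (1 + count) / (1 + n_perm)

    te_a, te_b, p_te = perm_p(te)
    g_a, g_b, p_gene = perm_p(gene)
    return CompartmentStats(mean_te_A=te_a, mean_te_B=te_b, mean_gene_A=g_a,
                            mean_gene_B=g_b, p_te=p_te, p_gene=p_gene)


# ---------------------------------------------------------------- IO


def write_contact_matrix(matrix: ContactMatrix, matrix_path, bins_path) -> None:
    np.savetxt(matrix_path, matrix.counts, fmt="%.6g", delimiter="\t")
    with open(bins_path, "w") as fh:
        for c, s, e in matrix.bins:
            fh.write(f"{c}\t{s}\t{e}\n")


def read_contact_matrix(matrix_path, bins_path) -> ContactMatrix:
    """Read a dense TSV matrix, or a 3-column sparse (i, j, count) file."""
    bins = []
    with open(bins_path) as fh:
        for line in fh:
            c, s, e = line.split()[:3]
            bins.append((c, int(s), int(e)))
    raw = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    if raw.shape[1] == 3 and raw.shape[0] != 3 and len(bins) != 3:
        counts = np.zeros((len(bins), len(bins)))
        for i, j, v in raw:
            counts[int(i), int(j)] = v
            counts[int(j), int(i)] = v
    else:
        counts = raw
    return ContactMatrix(bins=bins, counts=counts)
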