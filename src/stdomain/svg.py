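"""Spatially variable gene (SVG) detection within predicted domains.

A gene is an SVG of a spatial domain when it is differentially expressed
there (Wilcoxon rank-sum against all other spots, Benjamini-Hochberg
adjusted p < 0.05, fold change > 1.5 on back-transformed means), detected
in more than 80% of the domain's spots (in-fraction), and more prevalent
inside than in every lattice-neighboring domain (in/out fraction ratio
> 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import NormalizedExpression
from .training import lattice_pairs

ALPHA = 0.05
MIN_FOLD_CHANGE = 1.5
MIN_IN_FRACTION = 0.8
MIN_RATIO = 1.0


@dataclass
class SvgResult:
    domain: int
    gene: str
    adj_p: float
    fold_change: float
    in_fraction: float
    min_in_out_ratio: float
    passed: bool


def neighbor_domains(
    C, spot_index: np.ndarray, platform: str
) -> dict[int, set[int]]:
    """Domains sharing at least one lattice-adjacent spot pair.

    Adjacency uses the platform's closest-neighbor offsets (the same pairs
    the continuity loss reads).
    """
    C = np.asarray(C)
    ortho, diag = lattice_pairs(spot_index, platform)
    pairs = np.vstack([ortho, diag])
    out: dict[int, set[int]] = {int(lab): set() for lab in np.unique(C)}
    for i, j in pairs:
        a, b = int(C[i]), int(C[j])
        if a != b:
            out[a].add(b)
            out[b].add(a)
    return out


def detect_svg(
    counts_norm: NormalizedExpression,
    C,
    domain: int,
    neighbors: set[int],
    alpha: float = ALPHA,
    min_fold_change: float = MIN_FOLD_CHANGE,
    min_in_fraction: float = MIN_IN_FRACTION,
    min_ratio: float = MIN_RATIO,
) -> list[SvgResult]:
    """Score every gene of one domain against the four SVG filters."""
    from scipy.stats import mannwhitneyu
    from statsmodels.stats.multitest import multipletests

    C = np.asarray(C)
    in_mask = C == domain
    if not np.any(in_mask):
        raise ValueError(f"domain {domain} has no spots")
    missing = [nb for nb in neighbors if not np.any(C == nb)]
    if missing:
        raise ValueError(f"neighbor domain(s) {missing} absent from C")
    vals = counts_norm.values
    x_in = vals[in_mask]
    x_out = vals[~in_mask]
    if x_out.shape[0] == 0:
        raise ValueError("domain covers all spots; no outside reference")
    res = mannwhitneyu(x_in, x_out, alternative="two-sided", axis=0)
    pvals = np.atleast_1d(res.pvalue)
    adj_p = multipletests(pvals, method="fdr_bh")[1]
    mean_in = np.expm1(x_in).mean(axis=0)
    mean_out = np.expm1(x_out).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(mean_out > 0, mean_in / np.maximum(mean_out, 1e-300), np.inf)
    in_frac = (x_in > 0).mean(axis=0)
    ratios = np.full(vals.shape[1], np.inf)
    for nb in neighbors:
        nb_frac = (vals[C == nb] > 0).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(nb_frac > 0, in_frac / np.maximum(nb_frac, 1e-300), np.inf)
        r = np.where((nb_frac == 0) & (in_frac == 0), 1.0, r)
        ratios = np.minimum(ratios, r)
    results = []
    for g, name in enumerate(counts_norm.gene_names):
        passed = (
            adj_p[g] < alpha
            and fold[g] > min_fold_change
            and in_frac[g] > min_in_fraction
            and ratios[g] > min_ratio
        )
        results.append(
            SvgResult(
                domain=int(domain),
                gene=name,
                adj_p=float(adj_p[g]),
                fold_change=float(fold[g]),
                in_fraction=float(in_frac[g]),
                min_in_out_ratio=float(ratios[g]),
                passed=bool(passed),
            )
        )
    return results


def svg_table(results: list[SvgResult]):
    """SVG results as a DataFrame (one row per domain/gene pair)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "domain": r.domain,
                "gene": r.gene,
                "adj_p": r.adj_p,
                "fold_change": r.fold_change,
                "in_fraction": r.in_fraction,
                "min_in_out_ratio": r.min_in_out_ratio,
                "passed": r.passed,
            }
            for r in results
        ]
    )


def write_svg_tsv(results: list[SvgResult], path) -> None:
    svg_table(results).to_csv(path, sep="\t", index=False)
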