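"""Hand-built toy objects and independent oracle implementations."""

import itertools

import numpy as np

from stdomain import NormalizedExpression, PcaModel


def random_pca15(n_spots: int, n_genes: int = 20, seed: int = 0) -> PcaModel:
    """A synthetic 15-component PCA model over random expression values."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_spots, n_genes))
    mean = values.mean(axis=0)
    Q, _ = np.linalg.qr(rng.normal(size=(n_genes, 15)))
    return PcaModel(
        mean_vector=mean, loadings=Q, scores=(values - mean) @ Q, k=15
    )


def pair_counting_ari(U, V) -> float:
    """Brute-force adjusted Rand index over all spot pairs."""
    U, V = np.asarray(U), np.asarray(V)
    n = U.size
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        same_u, same_v = U[i] == U[j], V[i] == V[j]
        if same_u and same_v:
            a += 1
        elif same_u:
            c += 1
        elif same_v:
            d += 1
        else:
            b += 1
    total = a + b + c + d
    expected = (a + c) * (a + d) / total
    max_index = 0.5 * ((a + c) + (a + d))
    if max_index == expected:
        return 1.0
    return (a - expected) / (max_index - expected)


def svg_toy():
    """20 spots in two 10-spot domains, 10 genes, one true marker.

    gene0: perfect marker of domain 0.  gene1: strong but only in half of
    domain 0 (fails in-fraction).  gene2: expressed everywhere, higher in
    domain 0 (fails only the in/out fraction ratio, which is exactly 1).
    Remaining genes: constant background.
    """
    values = np.ones((20, 10))
    values[:, 0] = 0.0
    values[:10, 0] = 5.0
    values[:, 1] = 0.0
    values[:5, 1] = 5.0
    values[:10, 2] = 6.0
    values[10:, 2] = 3.0
    e = NormalizedExpression(
        values=values, gene_names=[f"g{j}" for j in range(10)]
    )
    C = np.repeat([0, 1], 10)
    return e, C
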