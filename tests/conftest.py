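import pytest

from stdomain import (
    FixtureSpec,
    build_image,
    build_spot_graph,
    filter_dataset,
    fit_pca,
    normalize,
    select_hvg,
    simulate_counts,
)


@pytest.fixture(scope="session")
def stripe_data():
    """The standard three-stripe staggered-lattice fixture (~300 spots)."""
    d, labels = simulate_counts(FixtureSpec())
    return d, labels


@pytest.fixture(scope="session")
def stripe_preprocessed(stripe_data):
    d, labels = stripe_data
    d = filter_dataset(d)
    e = select_hvg(normalize(d), 3000)
    return {
        "d": d,
        "labels": labels,
        "e": e,
        "p50": fit_pca(e, 50, gene_scope="hvg"),
        "p15": fit_pca(e, 15, gene_scope="hvg"),
        "graph": build_spot_graph(d.pixel_xy),
    }


import os
import sys

sys.path.insert(0, os.path.dirname(__file__))  # make _toys importable everywhere


@pytest.fixture(scope="session")
def stripe_image(stripe_preprocessed):
    pp = stripe_preprocessed
    return build_image(pp["e"], pp["d"], pp["p15"])


@pytest.fixture(scope="session")
def small_visium_image():
    """A compact staggered-lattice virtual image for network-level tests."""
    spec = FixtureSpec(rows=8, cols=8, n_genes=100, markers_per_domain=5, seed=3)
    d, labels = simulate_counts(spec)
    d = filter_dataset(d)
    e = select_hvg(normalize(d), 3000)
    p15 = fit_pca(e, 15, gene_scope="hvg")
    img = build_image(e, d, p15)
    return {"d": d, "labels": labels, "e": e, "p15": p15, "img": img}
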