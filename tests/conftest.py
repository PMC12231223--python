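import numpy as np
import pytest

import geckodiet as gd


@pytest.fixture(scope="session")
def reference_counts():
    """Published per-category F, N, V counts."""
    return gd.reference.composition_counts_frame()


@pytest.fixture(scope="session")
def reference_printed():
    """Published percentage and IRI columns, for cross-checking."""
    return gd.reference.composition_printed_frame()


@pytest.fixture(scope="session")
def reference_table(reference_counts):
    """Composition table recomputed from the published counts."""
    return gd.composition_from_aggregates(
        reference_counts, n_stomachs=gd.reference.N_STOMACHS
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset (51 specimens), volumes computed."""
    return gd.compute_volumes(gd.generate_dataset(seed=1))


def make_dataset(item_spec, groups=None):
    """Build a small dataset from {stomach_id: [(category, L, W), ...]}.

    ``groups`` optionally maps stomach ids to group labels (default
    female).  Morphometrics are filled with plausible constants.
    """
    specimens = []
    for i, sid in enumerate(item_spec):
        group = (groups or {}).get(sid, "female")
        specimens.append(
            gd.Specimen(specimen_id=sid, group=group, svl=100.0 + i, mw=20.0,
                        bm=20.0)
        )
    items = []
    for sid, rows in item_spec.items():
        for cat, length, width in rows:
            items.append(gd.PreyItem(specimen_id=sid, category=cat,
                                     length_mm=length, width_mm=width))
    return gd.assemble_dataset(specimens, items)


def random_small_dataset(rng, max_stomachs=5, max_categories=4):
    """Random tiny dataset for oracle-equivalence and invariant checks."""
    n_stomachs = int(rng.integers(1, max_stomachs + 1))
    cats = [f"cat{j}" for j in range(int(rng.integers(1, max_categories + 1)))]
    spec = {}
    for i in range(n_stomachs):
        n_items = int(rng.integers(1, 6))
        rows = []
        for _ in range(n_items):
            length = float(rng.uniform(0.5, 30.0))
            width = float(rng.uniform(0.2, min(length, 6.0)))
            rows.append((cats[int(rng.integers(0, len(cats)))], length, width))
        spec[f"s{i}"] = rows
    return make_dataset(spec)
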