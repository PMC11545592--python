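import numpy as np
import pandas as pd
import pytest

from dietmb.io import GROUP_FISH, GROUP_INVERT, PreyTable


def make_prey(counts, items=None, groups=None, samples=None) -> PreyTable:
    """Hand-build a small PreyTable from a nested list (samples x items)."""
    arr = np.asarray(counts)
    n_samples, n_items = arr.shape
    items = items or [f"Item{i} sp." for i in range(n_items)]
    samples = samples or [f"S{k}" for k in range(n_samples)]
    if groups is None:
        groups = {
            item: (GROUP_FISH if i < (n_items + 1) // 2 else GROUP_INVERT)
            for i, item in enumerate(items)
        }
    return PreyTable(pd.DataFrame(arr, index=samples, columns=items), dict(groups))


def random_prey(rng, n_samples=5, n_items=6) -> PreyTable:
    """Random small prey table with no empty samples."""
    counts = rng.integers(0, 50, size=(n_samples, n_items))
    counts[counts.sum(axis=1) == 0, 0] = 1
    return make_prey(counts)


# naive reference implementations (independent double-loop oracles)


def naive_foo(prey):
    out = {}
    for item in prey.items:
        n = 0
        for s in prey.sample_ids:
            if prey.counts.at[s, item] > 0:
                n += 1
        out[item] = (n, 100.0 * n / len(prey.sample_ids))
    return out


def naive_rra(prey):
    out = {}
    for item in prey.items:
        acc = 0.0
        for s in prey.sample_ids:
            acc += prey.counts.at[s, item] / prey.counts.loc[s].sum()
        out[item] = 100.0 * acc / len(prey.sample_ids)
    return out


def naive_psa(prey):
    out = {}
    for item in prey.items:
        num = 0.0
        den = 0.0
        for s in prey.sample_ids:
            if prey.counts.at[s, item] > 0:
                num += prey.counts.at[s, item]
                den += prey.counts.loc[s].sum()
        out[item] = 100.0 * num / den if den else float("nan")
    return out


@pytest.fixture
def tiny_prey():
    """3 samples x 3 items with easy hand-checkable numbers."""
    return make_prey(
        [[10, 60, 30], [0, 50, 30], [30, 10, 20]],
        items=["Zacco sp.", "Polypedilum sp.", "Ephemera sp."],
        groups={
            "Zacco sp.": GROUP_FISH,
            "Polypedilum sp.": GROUP_INVERT,
            "Ephemera sp.": GROUP_INVERT,
        },
        samples=["F1", "F2", "F3"],
    )
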