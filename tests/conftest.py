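import numpy as np
import pytest

from cueditscan.seqio import SiteWindow, UPSTREAM_LEN, DOWNSTREAM_LEN

BASES = "ACGU"


def random_window(rng: np.random.Generator, min_len: int = 26) -> SiteWindow:
    """A random window; lengths below 26 exercise the padding path."""
    total = int(rng.integers(min_len, 27)) if min_len < 26 else 26
    n_up_real = min(UPSTREAM_LEN, int(rng.integers(0, total)))
    n_down_real = min(DOWNSTREAM_LEN, total - 1 - n_up_real)
    up = "".join(rng.choice(list(BASES), size=n_up_real))
    down = "".join(rng.choice(list(BASES), size=n_down_real))
    n_pad_up = UPSTREAM_LEN - n_up_real
    n_pad_down = DOWNSTREAM_LEN - n_down_real
    return SiteWindow(gene="rand", c_pos=n_up_real + 1,
                      upstream="U" * n_pad_up + up,
                      downstream=down + "U" * n_pad_down,
                      n_pad_up=n_pad_up, n_pad_down=n_pad_down)


def full_random_window(rng: np.random.Generator) -> SiteWindow:
    up = "".join(rng.choice(list(BASES), size=UPSTREAM_LEN))
    down = "".join(rng.choice(list(BASES), size=DOWNSTREAM_LEN))
    return SiteWindow(gene="rand", c_pos=UPSTREAM_LEN + 1,
                      upstream=up, downstream=down)


def window_from(seq26: str) -> SiteWindow:
    """Unpadded window from a 26-nt string whose 16th residue is C."""
    assert len(seq26) == 26 and seq26[UPSTREAM_LEN] == "C"
    return SiteWindow(gene="fixed", c_pos=UPSTREAM_LEN + 1,
                      upstream=seq26[:UPSTREAM_LEN],
                      downstream=seq26[UPSTREAM_LEN + 1:])


@pytest.fixture(scope="session")
def motif_benchmark():
    """A modest planted-motif benchmark shared by classifier tests:
    200 positives at 1:3, split 70-30."""
    from cueditscan import benchmark as bench, ml, synthetic

    params = synthetic.MotifParams()
    bset, _ = synthetic.make_benchmark(200, 3, params, seed=11)
    train, test = bench.split_train_test(list(bset.sites), 0.7, seed=11)
    cfg = ml.TrainingConfig(seed=11, n_estimators=300)
    X, y = ml.build_training_set(train, cfg)
    model = ml.train_model(X, y, cfg)
    return {"params": params, "train": train, "test": test,
            "model": model, "cfg": cfg}
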