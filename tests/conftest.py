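import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pytest

from locuskit import sumstats, synthetic


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(n_samples=400, n_variants=60, rho=0.8, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_config):
    return synthetic.simulate_panel(small_config)


@pytest.fixture(scope="session")
def harmonized(small_panel, small_config):
    raw, _ = synthetic.simulate_sumstats(small_panel, small_config, dialect="metal")
    return sumstats.harmonize(raw, trait="demo")


@pytest.fixture()
def gtf_path(tmp_path):
    path = tmp_path / "fixture.gtf"
    synthetic.write_gtf_fixture(synthetic.default_gene_spec(), path)
    return path


def brute_force_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Independent LD oracle: mean-impute, then plain Pearson r squared."""
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    for v in (x, y):
        miss = np.isnan(v)
        if miss.all():
            return np.nan
        v[miss] = v[~miss].mean()
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def greedy_loci_oracle(table, threshold=5e-8, half_width=1_000_000):
    """Independent exhaustive re-statement of the locus clumping rule.

    Works on a list of plain record dicts, re-scanning all remaining
    records at every step (no shared code with locuskit.loci).
    """
    chrom_order = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}
    records = [
        dict(r)
        for r in table.to_dict("records")
        if r["p"] < threshold
    ]
    out = []
    while records:
        best = min(
            records,
            key=lambda r: (
                r["p"],
                chrom_order.get(str(r["chrom"]), 100),
                str(r["chrom"]),
                r["pos"],
                str(r["snp_id"]),
            ),
        )
        lo, hi = max(1, best["pos"] - half_width), best["pos"] + half_width
        # a less significant window yields ground to earlier ones
        for c, s, e, _ in out:
            if c != str(best["chrom"]):
                continue
            if e < best["pos"] and e + 1 > lo:
                lo = e + 1
            if s > best["pos"] and s - 1 < hi:
                hi = s - 1
        out.append((str(best["chrom"]), lo, hi, str(best["snp_id"])))
        records = [
            r
            for r in records
            if not (str(r["chrom"]) == str(best["chrom"]) and lo <= r["pos"] <= hi)
        ]
    return out


def random_sumstats_table(rng, max_rows=400):
    """Random harmonized-shape table for clumping property tests."""
    import pandas as pd

    n = int(rng.integers(20, max_rows))
    chroms = rng.choice(["1", "2", "X"], size=n)
    pos = rng.integers(1, 30_000_000, size=n)
    neglogp = rng.uniform(0, 12, size=n)
    p = 10.0 ** -neglogp
    return pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n)],
            "chrom": chroms,
            "pos": pos,
            "p": p,
            "neglog10p": neglogp,
        }
    )
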