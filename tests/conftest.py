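import numpy as np
import pandas as pd
import pytest

from trimr.instruments import HarmonizedSet


def make_sumstats(rows, columns=("snp", "effect_allele", "other_allele",
                                 "beta", "se", "pval", "eaf", "n")):
    """Build a summary-statistics frame from tuples (missing columns padded)."""
    df = pd.DataFrame(rows, columns=columns[: len(rows[0])])
    for col in columns:
        if col not in df.columns:
            df[col] = np.nan
    return df[list(columns)]


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


@pytest.fixture
def harmonized_factory():
    """Random harmonized instrument sets with reproducible draws."""

    def _make(k=10, seed=0, beta_exp_scale=0.1, se_out_scale=0.02):
        rng = np.random.default_rng(seed)
        beta_exp = rng.uniform(0.05, 0.2, k) * beta_exp_scale / 0.1
        se_exp = rng.uniform(0.005, 0.02, k)
        beta_out = rng.normal(0.0, 0.05, k)
        se_out = rng.uniform(0.5, 1.5, k) * se_out_scale
        return HarmonizedSet(
            snp_ids=np.array([f"rs{i}" for i in range(k)], dtype=object),
            beta_exp=beta_exp, se_exp=se_exp,
            beta_out=beta_out, se_out=se_out,
            eaf_exp=rng.uniform(0.1, 0.5, k),
        )

    return _make
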