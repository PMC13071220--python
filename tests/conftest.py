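import numpy as np
import pandas as pd
import pytest

from targetmr.sumstats import SUMSTAT_COLUMNS, TraitMeta, build_table
from targetmr.synthetic import DrugTargetConfig, simulate_drug_target_study

CONTINUOUS_META = TraitMeta(
    "hba1c", "glycated haemoglobin", "continuous", "mmol/mol",
    sample_size=344_182,
)
BINARY_META = TraitMeta(
    "t2d", "type 2 diabetes", "log_odds", "log-odds",
    sample_size=1_812_017, n_cases=242_283,
)

ROW_DEFAULTS = {
    "chrom": "1",
    "effect_allele": "A",
    "other_allele": "G",
    "eaf": 0.3,
    "beta": 0.1,
    "se": 0.02,
    "pvalue": 1e-4,
    "n": None,
}


def make_table(rows, meta=CONTINUOUS_META):
    """Build a SummaryStatTable from partial row dicts with defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(ROW_DEFAULTS)
        rec.setdefault("variant_id", f"rs{i + 1}")
        rec["pos"] = 1_000_000 * (i + 1)
        rec.update(row)
        full.append(rec)
    df = pd.DataFrame(full)
    for col in SUMSTAT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return build_table(meta, df[SUMSTAT_COLUMNS])


@pytest.fixture(scope="session")
def drug_study():
    """One planted drug-target study shared by read-only tests."""
    return simulate_drug_target_study(DrugTargetConfig(seed=7))
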