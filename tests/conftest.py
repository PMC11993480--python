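import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tsscore.cohort import Cohort
from tsscore.scoring import SUBSCORE_FIELDS
from tsscore.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def decompose_total(total: int) -> dict:
    """Any valid sub-score vector summing to ``total`` (greedy fill)."""
    caps = {name: (2 if name in ("tad_score", "quadrant_score") else 1) for name in SUBSCORE_FIELDS}
    out = {}
    remaining = total
    for name, cap in caps.items():
        take = min(cap, remaining)
        out[name] = take
        remaining -= take
    assert remaining == 0, f"total {total} exceeds 8"
    return out


def make_cohort(totals, outcomes) -> Cohort:
    """Cohort fixture from parallel lists of totals and outcomes."""
    rows = []
    for i, (t, y) in enumerate(zip(totals, outcomes)):
        row = {"id": f"X{i}", "outcome": int(y), "tss_total": int(t)}
        row.update(decompose_total(int(t)))
        rows.append(row)
    return Cohort(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohorts():
    """100 cohorts of n=586 from the default (study-condition) generator."""
    return [generate_cohort(GeneratorConfig(seed=1000 + i)) for i in range(100)]


@pytest.fixture(scope="session")
def model_cohort_5000():
    """One model-mode cohort large enough for calibration checks."""
    return generate_cohort(GeneratorConfig(n=5000, mode="model_based", seed=77))


def brute_force_auc(y, risk) -> float:
    """Oracle: tie-corrected concordance probability over all outcome pairs."""
    y = np.asarray(y)
    risk = np.asarray(risk, dtype=float)
    pos = risk[y == 1]
    neg = risk[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
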