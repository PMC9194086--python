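import numpy as np
import pandas as pd
import pytest

import leukopred as lp


@pytest.fixture(scope="session")
def planted_cohort():
    """202-gene cohort with one up- and one down-regulated planted marker."""
    return lp.simulate_cohort(lp.SynthConfig(n_genes=202, seed=1))


def prepare(cohort, n_non_validation=6):
    """Split, log-transform, scale on train; return the pieces stages need."""
    split = lp.split_cohort(cohort.metadata, n_non_validation)
    logm = lp.log_transform(cohort.matrix)
    train = [s for s in logm.sample_ids if split[s] == "train"]
    valid = [s for s in logm.sample_ids if split[s] == "validation"]
    scaler = lp.fit_scaler(logm, train)
    z = lp.apply_scaler(logm, scaler)
    meta = cohort.metadata.set_index("sample_id")
    return {
        "split": split,
        "logm": logm,
        "scaler": scaler,
        "z": z,
        "z_train": z.subset_samples(train),
        "z_valid": z.subset_samples(valid),
        "y_train": meta.loc[train, "group"].to_numpy(),
        "y_valid": meta.loc[valid, "group"].to_numpy(),
        "train": train,
        "valid": valid,
    }


def study_metadata():
    """Metadata matching the study composition: 26 obstructive samples of
    which the first 7 are imaging-identifiable, and 22 non-obstructive."""
    rng = np.random.default_rng(42)
    rows = []
    for i in range(26):
        rows.append(
            {
                "sample_id": f"OB{i + 1:03d}",
                "group": "obstructive",
                "age_days": float(rng.lognormal(np.log(7.5), 1.2)),
                "weight_kg": 3.2,
                "imaging_identifiable": i < 7,
            }
        )
    for i in range(22):
        rows.append(
            {
                "sample_id": f"NO{i + 1:03d}",
                "group": "non_obstructive",
                "age_days": float(rng.lognormal(np.log(120.0), 1.6)),
                "weight_kg": 5.2,
                "imaging_identifiable": False,
            }
        )
    return pd.DataFrame(rows)


def holm_oracle(p):
    """Independent Holm oracle: adjusted_i = smallest level at which the
    step-down rejection procedure (walk the ascending p-values, stop at the
    first failure of p_(j) <= alpha/(m-j+1)) rejects hypothesis i."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")

    def rejected_at(alpha):
        rej = np.zeros(m, bool)
        for j in range(m):
            if p[order[j]] * (m - j) <= alpha:
                rej[order[j]] = True
            else:
                break
        return rej

    candidates = sorted({min(1.0, p[order[j]] * (m - j)) for j in range(m)})
    adjusted = np.ones(m)
    for alpha in reversed(candidates):
        adjusted[rejected_at(alpha)] = alpha
    return adjusted
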