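import numpy as np
import pandas as pd
import pytest

import prseval as pe


# ---------------------------------------------------------------------------
# independent oracles (brute force / direct evaluation), used across modules

def auc_pair_counting(scores, labels):
    """AUC by exhaustive case-control pair counting, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1][:, None]
    controls = scores[labels == 0][None, :]
    gt = (cases > controls).sum()
    eq = (cases == controls).sum()
    return (gt + 0.5 * eq) / (cases.size * controls.size)


def residual_incidence_direct(incidence, annual_death):
    """Direct evaluation of the telescoping residual-lifetime-incidence sum:
    each later interval's incidence weighted by all earlier survival and
    disease-free factors; terminal interval contributes once."""
    inc = np.asarray(incidence, dtype=float)
    surv = (1.0 - np.asarray(annual_death, dtype=float)) ** 5
    k = len(inc)
    out = np.empty(k)
    for d in range(k):
        total = inc[d]
        s = 1.0
        f = 1.0
        for j in range(d + 1, k):
            s *= surv[j - 1]
            f *= 1.0 - inc[j - 1]
            total += inc[j] * s * f
        out[d] = total
    return out


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study reused by read-only tests."""
    cfg = pe.SimulationConfig(n_cases=250, n_controls=600, n_snps=40, seed=42)
    return pe.simulate_case_control_study(cfg)


@pytest.fixture(scope="session")
def small_scores(small_study):
    st = small_study
    match = pe.match_variants(st.weights, st.panel)
    raw = pe.compute_prs(st.panel, st.weights, match)
    std = pe.standardize(raw, st.cohort)
    return st, match, std


def toy_panel(dosage_rows, chrom=None, ref="A", alt="G"):
    """Panel from an individuals x variants list of dosage rows."""
    d = np.asarray(dosage_rows, dtype=float)
    n, m = d.shape
    meta = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": np.arange(100, 100 + m),
            "ref": [ref] * m,
            "alt": [alt] * m,
        }
    )
    ids = [f"S{i}" for i in range(n)]
    return pe.DosagePanel(individual_ids=pd.Index(ids), variants=meta, dosages=d)


def toy_weights(panel, weights, effect="alt"):
    """Weight table aligned to a panel, effect allele = panel alt (or ref)."""
    v = panel.variants
    eff = v["alt"] if effect == "alt" else v["ref"]
    oth = v["ref"] if effect == "alt" else v["alt"]
    return pe.VariantWeightTable(
        variants=pd.DataFrame(
            {
                "chrom": v["chrom"],
                "pos": v["pos"],
                "effect_allele": eff,
                "other_allele": oth,
                "weight": np.asarray(weights, dtype=float),
            }
        )
    )


def toy_cohort(status, **cols):
    """Cohort from a case/control vector; covariates default to zeros."""
    status = np.asarray(status)
    n = len(status)
    base = {
        "individual_id": [f"S{i}" for i in range(n)],
        "status": np.where(status == 1, "case", "control"),
        "sex": cols.get("sex", np.zeros(n, dtype=int)),
        "age_at_sampling": cols.get("age", np.full(n, 60.0)),
        "age_at_onset": cols.get(
            "aao", np.where(status == 1, 60.0, np.nan)
        ),
        "PC1": cols.get("pc1", np.zeros(n)),
        "PC2": cols.get("pc2", np.zeros(n)),
        "PC3": cols.get("pc3", np.zeros(n)),
    }
    return pe.Cohort(samples=pd.DataFrame(base))
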