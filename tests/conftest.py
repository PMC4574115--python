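import numpy as np
import pandas as pd
import pytest

import senesig as sg


@pytest.fixture(scope="session")
def two_experiment_sim():
    """A well-powered two-experiment simulation with DMP calls and delta maps.

    Uses a replicate-noise concentration matching the near-perfect replicate
    concordance of real arrays so that planted sites are recoverable at the
    standard thresholds.
    """
    params = sg.SimParams(n_probes=4000, nu=500.0, seed=11)
    beta, samples, annotation, truth = sg.simulate_two_experiment_senescence(params)
    deltas = {}
    for e in ("exp1", "exp2"):
        ep = samples.samples_in("EP", e)
        ds = samples.samples_in("DS", e)
        deltas[e] = beta.values[ds].mean(axis=1) - beta.values[ep].mean(axis=1)
    calls = {
        e: sg.call_dmps(beta, samples, "EP", "DS", experiment=e)
        for e in ("exp1", "exp2")
    }
    return {
        "params": params,
        "beta": beta,
        "samples": samples,
        "annotation": annotation,
        "truth": truth,
        "deltas": deltas,
        "calls": calls,
    }


@pytest.fixture(scope="session")
def cohort_sim():
    """Standalone cohort simulation at the default study conditions."""
    params = sg.SimParams(n_probes=2000, seed=3)
    beta, samples, genotypes, expression, truth = sg.simulate_cohort(params)
    return {
        "params": params,
        "beta": beta,
        "samples": samples,
        "genotypes": genotypes,
        "expression": expression,
        "truth": truth,
    }


def make_beta(values, probes=None, samples=None) -> sg.BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return sg.BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


def make_annotation(rows) -> sg.ProbeAnnotation:
    """rows: list of (probe_id, chrom, pos, gene, feature_class, flags)."""
    return sg.ProbeAnnotation(
        pd.DataFrame(
            [
                {
                    "chrom": c, "pos": p, "gene": g, "feature_class": fc,
                    "flags": frozenset(fl),
                }
                for _, c, p, g, fc, fl in rows
            ],
            index=pd.Index([r[0] for r in rows], name="probe_id"),
        )
    )
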