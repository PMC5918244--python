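import numpy as np
import pytest

import citfit as cf


def make_effect(
    name: str,
    mu: float,
    sd: float = 0.005,
    n: int = 10,
    seed: int = 0,
    b_reps: int = 10_000,
    ara_mu: float = 1.0,
    ara_sd: float = 0.003,
) -> cf.CombinedEffect:
    """Combined effect for a strain whose Cit competitions center on mu."""
    rng = cf.strain_rng(seed, name)
    cit = tuple(rng.normal(mu, sd, n))
    ara = tuple(rng.normal(ara_mu, ara_sd, n))
    return cf.combined_cit_effect(
        cf.ReplicateSet(name, cit),
        cf.ReplicateSet(name, ara, "ara_marker"),
        b_reps=b_reps,
        seed=cf.strain_rng(seed, name + "/boot"),
        strain=name,
    )


def constant_effect(name: str, value: float, b_reps: int = 9999) -> cf.CombinedEffect:
    """Degenerate effect whose bootstrap draws are all exactly ``value``."""
    boot = cf.BootstrapResult(
        point=value, b_reps=b_reps, ci_level=0.95, ci_lo=value, ci_hi=value,
        draws=np.full(b_reps, value),
    )
    return cf.CombinedEffect(strain=name, w_combined=value, boot=boot, n_cit=2, n_ara=2)


@pytest.fixture(scope="session")
def mimic_bundle():
    """One realization of the four-epoch study-mimic lineage (seed 42)."""
    spec = cf.LineageSimSpec(seed=42)
    metadata, newick, competition = cf.simulate_lineage_study(spec)
    effects = cf.combined_effects_from_table(competition, b_reps=10_000, seed=42)
    records = [
        cf.StrainRecord(
            strain=r.strain, generation=r.generation,
            effect=effects[r.strain], divergence=r.divergence,
        )
        for r in metadata.itertuples()
    ]
    return {
        "spec": spec, "metadata": metadata, "newick": newick,
        "competition": competition, "effects": effects, "records": records,
    }


@pytest.fixture(scope="session")
def mimic_clusters(mimic_bundle):
    ordering = cf.LineageOrdering(
        ordered=sorted(mimic_bundle["records"], key=lambda r: (r.generation, r.strain))
    )
    return cf.cluster_adjacent(ordering)
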