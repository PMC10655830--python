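import numpy as np
import pandas as pd
import pytest

from vinevigor import qtl
from vinevigor.synthetic_data import (QtlSpec, SimConfig, _nearest_marker,
                                      qtl_class_effects,
                                      simulate_genetic_map,
                                      simulate_progeny_genotypes)


@pytest.fixture(scope="session")
def small_map():
    """One 50-cM chromosome, markers every 5 cM."""
    cfg = SimConfig(seed=1, chromosomes=[("chr1", 50.0, 25_000_000)],
                    marker_spacing_cM=5.0)
    return simulate_genetic_map(cfg)


@pytest.fixture(scope="session")
def study():
    """A genome-scale instance: 19 chromosomes, ~440 markers, 200 progeny."""
    cfg = SimConfig(seed=11, n_progeny=200, marker_spacing_cM=2.5)
    gmap = simulate_genetic_map(cfg)
    geno = simulate_progeny_genotypes(gmap, 200, 11)
    return gmap, geno


@pytest.fixture(scope="session")
def study_scanner(study):
    gmap, geno = study
    return qtl.MarkerRegressionScanner(geno, gmap)


def planted_trait(geno, gmap, specs, seed, total_var=1.0):
    """Unit-variance per-genotype trait with the given planted QTLs."""
    rng = np.random.default_rng(seed)
    frac = sum(s.fraction_variance for s in specs)
    y = rng.normal(0.0, np.sqrt(max(total_var * (1 - frac), 0.0)), len(geno))
    idxmap = {c: i for i, c in enumerate(qtl.GENOTYPE_CLASSES)}
    for s in specs:
        marker = _nearest_marker(gmap, s.chromosome, s.position_cM)
        effects = qtl_class_effects(s, total_var)
        y = y + effects[geno[marker].map(idxmap).to_numpy()]
    return pd.Series(y, index=geno.index)


def planted_marker(gmap, spec):
    return _nearest_marker(gmap, spec.chromosome, spec.position_cM)
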