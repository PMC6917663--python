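import numpy as np
import pytest

from ltqtl import linkage as lk
from ltqtl import sim


def single_qtl_config(seed: int = 0, pve: float = 0.25, n: int = 189,
                      length_cm: float = 100.0, spacing_cm: float = 5.0,
                      qtl_cm: float = 50.0) -> sim.CrossSimConfig:
    """One chromosome, evenly spaced markers, one QTL of given variance share."""
    a = sim.calibrate_additive_effects({"q": pve})["q"]
    n_mark = int(length_cm / spacing_cm) + 1
    cm = tuple(round(i * spacing_cm, 6) for i in range(n_mark))
    bp = tuple(int(x * 2e5) + 1 for x in cm)
    return sim.CrossSimConfig(
        n_individuals=n,
        chromosomes=[sim.ChromSpec("1", cm, bp)],
        qtls=[sim.QTLSpec("1", qtl_cm, a, -0.5 * a, name="q")],
        polygenic_sd=0.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def qtl_cross():
    """A simulated single-QTL cross reused across read-only tests."""
    cfg = single_qtl_config(seed=3)
    f2 = sim.simulate_f2(cfg)
    return cfg, f2


@pytest.fixture(scope="session")
def qtl_scan(qtl_cross):
    """Genotype probabilities, family phenotype and IM scan for the cross."""
    from ltqtl import phenotype as ph

    cfg, f2 = qtl_cross
    pheno = sim.simulate_family_phenotypes(f2, cfg)
    y = ph.aggregate_families(ph.ltii_table(pheno))
    scfg = lk.ScanConfig(seed=1, n_permutations=100)
    probs = lk.genotype_probabilities(f2.genotypes, f2.gmap, scfg)
    scan = lk.scan_im(probs, y, scfg)
    return {"config": scfg, "probs": probs, "phenotype": y, "scan": scan, "f2": f2}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
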