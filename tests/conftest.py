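import numpy as np
import pytest

from wepistasis import GenotypeMatrix, MethylationMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_cohort():
    """Five fully observed subjects, 2 SNPs, 2 CpGs, TG phenotypes."""
    ids = [f"s{i}" for i in range(1, 6)]
    geno = GenotypeMatrix(ids, ["rs1", "rs2"], np.array(
        [[0, 1], [1, 2], [2, 0], [0, 1], [1, 1]], dtype=float))
    meth = MethylationMatrix(ids, ["cg1", "cg2"], np.array(
        [[0.1, 0.8], [0.2, 0.9], [0.85, 0.15], [0.9, 0.2], [0.15, 0.85]]))
    tg = np.array([
        [200.0, 220.0, 120.0, 140.0],  # delta 0.381 -> responder
        [100.0, 100.0, 90.0, 90.0],    # delta 0.10  -> non-responder
        [300.0, 280.0, 150.0, 130.0],  # delta 0.517 -> responder
        [100.0, 100.0, 120.0, 120.0],  # delta -0.20 -> non-responder
        [100.0, 100.0, 70.0, 70.0],    # delta 0.30 exactly -> non-responder
    ])
    pheno = PhenotypeTable(ids, tg)
    return geno, meth, pheno
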