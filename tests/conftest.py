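import numpy as np
import pytest

from mrkit import HarmonizedInstrument, SnpAssociation


def make_instruments(bx, by, sy, sx=None, eaf=None, palindromic=False):
    """Build usable harmonized instruments from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    eaf = np.full_like(bx, 0.3) if eaf is None else np.asarray(eaf, dtype=float)
    return [
        HarmonizedInstrument(
            rsid=f"rs{i + 1}",
            effect_allele="A",
            beta_exposure=float(bx[i]),
            se_exposure=float(sx[i]),
            beta_outcome=float(by[i]),
            se_outcome=float(sy[i]),
            eaf_exposure=float(eaf[i]),
            eaf_outcome=float(eaf[i]),
            palindromic=palindromic,
            action_taken="kept",
        )
        for i in range(len(bx))
    ]


def random_instruments(rng, k=None):
    """A random but well-conditioned instrument set for oracle comparisons."""
    if k is None:
        k = int(rng.integers(3, 30))
    bx = rng.uniform(0.03, 0.2, size=k) * rng.choice([-1, 1], size=k)
    by = rng.normal(0.1 * bx, 0.01)
    sy = rng.uniform(0.002, 0.02, size=k)
    sx = rng.uniform(0.002, 0.01, size=k)
    return make_instruments(bx, by, sy, sx)


def make_snp(rsid="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
             beta=0.1, se=0.01, pval=1e-10, n=50_000):
    return SnpAssociation(rsid, chrom, pos, ea, oa, eaf, beta, se, pval, n)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
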