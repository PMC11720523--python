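import numpy as np
import pytest

from xherit import GenotypeSet, Pedigree


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Sire M, dam F, daughter D, son O (of F with unknown sire)."""
    return Pedigree.from_records([
        ("M", "0", "0", "m"), ("F", "0", "0", "f"),
        ("D", "M", "F", "f"), ("O", "0", "F", "m")])


@pytest.fixture
def eight_animal_pedigree() -> Pedigree:
    """Mixed-sex three-generation pedigree used by the gene-dropping oracle."""
    return Pedigree.from_records([
        ("M1", "0", "0", "m"), ("F1", "0", "0", "f"),
        ("M2", "0", "0", "m"), ("F2", "0", "0", "f"),
        ("D1", "M1", "F1", "f"), ("S1", "M1", "F1", "m"),
        ("D2", "M2", "D1", "f"), ("S2", "S1", "F2", "m")])


def make_genotypes(calls, sex, is_x=None, coding="raw", chrom=None, pos=None):
    """Small GenotypeSet helper for hand-constructed matrices."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    if is_x is None:
        is_x = np.zeros(m, bool)
    is_x = np.asarray(is_x, bool)
    if chrom is None:
        chrom = np.where(is_x, "X", "1")
    return GenotypeSet(
        ids=np.array([f"a{i}" for i in range(n)], object),
        sex=np.asarray(sex, object),
        snp=np.array([f"s{j}" for j in range(m)], object),
        chrom=np.asarray(chrom, object),
        pos=(np.arange(1, m + 1) * 1e5 if pos is None
             else np.asarray(pos, float)),
        allele_a=np.array(["A"] * m, object),
        allele_b=np.array(["B"] * m, object),
        is_x=is_x, calls=calls, coding=coding)


@pytest.fixture
def geno_factory():
    return make_genotypes
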