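import numpy as np
import pytest

from radpop.core import GenotypeMatrix, LocusInfo, PopulationMap, default_tag_id

_BASES = "ACGT"


def make_gm(
    calls,
    samples=None,
    populations=None,
    contig="chr1",
    positions=None,
    tag_ids=None,
    ref_alt=None,
):
    """Build a small GenotypeMatrix from a nested list of dosage codes
    (-1 = missing)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    samples = samples or [f"s{i + 1}" for i in range(n)]
    positions = positions or [37 * j + 1 for j in range(L)]
    loci = []
    for j in range(L):
        ref, alt = ref_alt[j] if ref_alt else ("A", "G")
        loci.append(
            LocusInfo(
                locus_id=f"{contig}_{positions[j]}",
                contig=contig,
                position=positions[j],
                tag_id=tag_ids[j] if tag_ids else default_tag_id(contig, positions[j]),
                ref_allele=ref,
                alt_allele=alt,
            )
        )
    return GenotypeMatrix(
        samples=samples, loci=loci, calls=calls, populations=populations
    )


@pytest.fixture
def toy_gm():
    """4 samples x 3 loci, one missing call."""
    return make_gm(
        [[0, 1, 2], [1, 1, 0], [2, 0, -1], [0, 2, 1]],
        populations=["A", "A", "B", "B"],
    )


@pytest.fixture
def toy_pm(toy_gm):
    return PopulationMap(
        assignment={s: p for s, p in zip(toy_gm.samples, toy_gm.populations)},
        replicate_pairs=[],
    )
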