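import numpy as np
import pytest

from isomirshift.annotations import HairpinLocus, MatureAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_locus():
    """A 72-nt hairpin with both arms annotated at fixed positions."""
    rs = np.random.default_rng(7)
    seq = "".join(rs.choice(list("ACGU"), size=72))
    return HairpinLocus(
        locus_id="hsa-mir-T",
        name="mir-T",
        sequence=seq,
        matures=[
            MatureAnnotation("miR-T-5p", "5p", 12, 34),
            MatureAnnotation("miR-T-3p", "3p", 38, 60),
        ],
    )


@pytest.fixture
def toy_catalog(toy_locus, rng):
    """Three hairpins with distinct random sequences."""
    catalog = [toy_locus]
    for i in range(2):
        seq = "".join(rng.choice(list("ACGU"), size=72))
        catalog.append(
            HairpinLocus(
                locus_id=f"hsa-mir-U{i}",
                name=f"mir-U{i}",
                sequence=seq,
                matures=[
                    MatureAnnotation(f"miR-U{i}-5p", "5p", 12, 34),
                    MatureAnnotation(f"miR-U{i}-3p", "3p", 38, 60),
                ],
            )
        )
    return catalog
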