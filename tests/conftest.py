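import pytest

from mirstart import Hairpin

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def perfect_stem(arm: str = "GCGAUCGGCAUGCUAGCAGCAU", loop: int = 6,
                 f5: int = 8, f3: int = 8, mature_start: int | None = None,
                 mature_len: int = 22, hid: str = "stem") -> Hairpin:
    """Hairpin whose 5' arm pairs its reverse complement exactly."""
    seq = "A" * f5 + arm + "A" * loop + revcomp(arm) + "A" * f3
    struct = "." * f5 + "(" * len(arm) + "." * loop + ")" * len(arm) + "." * f3
    return Hairpin(id=hid, sequence=seq, structure=struct,
                   mature_start=mature_start, mature_len=mature_len)


def bulged_stem(arm: str = "GCGAUCGGCAUGCUAGCA", bulge_after: int = 3,
                loop: int = 6, f5: int = 8, f3: int = 8) -> Hairpin:
    """Perfect stem with one extra unpaired base on the 5' arm after
    arm position ``bulge_after``."""
    arm5 = arm[:bulge_after] + "A" + arm[bulge_after:]
    db5 = "(" * bulge_after + "." + "(" * (len(arm) - bulge_after)
    seq = "A" * f5 + arm5 + "A" * loop + revcomp(arm) + "A" * f3
    struct = "." * f5 + db5 + "." * loop + ")" * len(arm) + "." * f3
    return Hairpin(id="bulge", sequence=seq, structure=struct)


def internal_loop_stem(f5: int = 8, f3: int = 8, loop: int = 6) -> Hairpin:
    """Stem with a symmetric 2x2 internal loop after the third pair."""
    p_a, mis5, p_b = "GCG", "AA", "GCGCAUGC"
    mis3 = "CC"  # faces the AA run, non-complementary
    arm5 = p_a + mis5 + p_b
    arm3 = revcomp(p_b) + mis3 + revcomp(p_a)
    seq = "A" * f5 + arm5 + "A" * loop + arm3 + "A" * f3
    struct = (
        "." * f5 + "(((" + ".." + "(" * len(p_b) + "." * loop
        + ")" * len(p_b) + ".." + ")))" + "." * f3
    )
    return Hairpin(id="iloop", sequence=seq, structure=struct)


@pytest.fixture
def stem_hairpin():
    return perfect_stem()


@pytest.fixture
def stem_factory():
    return perfect_stem


@pytest.fixture
def bulged_hairpin():
    return bulged_stem()


@pytest.fixture
def internal_loop_hairpin():
    return internal_loop_stem()
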