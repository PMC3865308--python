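import pytest

from ampliconid import references
from ampliconid.amplicondb import build_reference_db, concretize, reverse_complement


@pytest.fixture(scope="session")
def fwd():
    return references.forward_primer()


@pytest.fixture(scope="session")
def rev():
    return references.reverse_primer()


@pytest.fixture(scope="session")
def mammal_db():
    return references.mammal_reference_db()


@pytest.fixture(scope="session")
def wrapped_records(fwd, rev):
    """The bundled targets re-wrapped with primer sites and flanks, as they
    would appear in a reference mitogenome fragment."""
    return [
        (
            sp.replace(" ", "_"),
            f"species={sp}",
            "AAA" + fwd.sequence + target + reverse_complement(concretize(rev.sequence)) + "AAA",
        )
        for sp, target in references.MAMMAL_TARGETS.items()
    ]


@pytest.fixture(scope="session")
def built_db(wrapped_records, fwd, rev):
    db, skips = build_reference_db(wrapped_records, fwd, rev)
    assert not skips
    return db


def levenshtein_oracle(a: str, b: str) -> int:
    """Independent quadratic DP edit distance (unit costs), used as the
    reference oracle for all distance computations."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]
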