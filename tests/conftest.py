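import random

import pytest

from paskscan.motif import MotifConfig, ProteinSequence, scan_sequence, window_qualifies


@pytest.fixture
def default_config():
    return MotifConfig()


@pytest.fixture
def rng():
    return random.Random(20240613)


def naive_scan(protein: ProteinSequence, config: MotifConfig):
    """Independent oracle: recount every window from scratch."""
    seq = protein.residues
    w = config.window_length
    hits = []
    for start0 in range(len(seq) - w + 1):
        if window_qualifies(seq[start0 : start0 + w], config):
            hits.append((start0 + 1, start0 + w))
    return hits


def random_protein(rng: random.Random, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> ProteinSequence:
    return ProteinSequence(
        identifier=f"rand_{length}_{rng.randrange(10**9)}",
        residues="".join(rng.choice(alphabet) for _ in range(length)),
    )
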