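from __future__ import annotations

import pytest

from lncpep.seqcore import _CODON_TO_AA
from lncpep.synthdata import simulate

# deterministic reverse translation: first codon (alphabetically) per residue
_AA_TO_CODON: dict[str, str] = {}
for codon in sorted(_CODON_TO_AA):
    aa = _CODON_TO_AA[codon]
    _AA_TO_CODON.setdefault(aa, codon)


def dna_for_protein(protein: str, stop: bool = True) -> str:
    """Encode a protein with a fixed codon choice (plus a stop by default)."""
    nt = "".join(_AA_TO_CODON[aa] for aa in protein)
    return nt + ("TAA" if stop else "")


@pytest.fixture(scope="session")
def dataset():
    """A complete seeded synthetic dataset shared across test modules."""
    return simulate(seed=1, n_transcripts=100)
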