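"""Reference sequence handling.

The package does not ship the human rCRS sequence; analyses that need base
identities accept any user-supplied FASTA.  For simulation and testing a
deterministic *synthetic* stand-in reference of the same length is generated
here.  Its base composition loosely mimics the mitochondrial genome
(slightly AC-rich heavy strand) but the sequence itself carries no
biological meaning.
"""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import numpy as np

from .genome import GENOME_LENGTH

_SYNTHETIC_SEED = 16569  # fixed: the synthetic reference is a package constant
_CACHE: dict[int, str] = {}


def synthetic_rcrs(length: int = GENOME_LENGTH) -> str:
    """Deterministic synthetic mitochondrial reference sequence.

    Same output on every call and every platform; used wherever a concrete
    base string is required but the real reference is not available.
    """
    if length not in _CACHE:
        rng = np.random.default_rng(_SYNTHETIC_SEED)
        bases = np.array(list("ACGT"))
        probs = np.array([0.31, 0.31, 0.13, 0.25])  # mtDNA-like composition
        _CACHE[length] = "".join(rng.choice(bases, size=length, p=probs))
    return _CACHE[length]


def read_fasta(path) -> str:
    """Read the first record of a FASTA file as an uppercase string."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_fasta(seq: str, path, name: str = "chrM") -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(path), "fasta")
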