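"""Shared fixtures and independent test oracles.

The window-enumeration oracle here is deliberately self-contained (its
own IUPAC table, plain string slicing) so scanner tests compare two
independent routes to the same answer.
"""

from __future__ import annotations

import numpy as np
import pytest

from cregulon import synthetic_data as synth

# independent IUPAC expansion table (not imported from the package)
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "M": "AC", "R": "AG", "W": "AT", "S": "CG", "Y": "CT", "K": "GT",
    "V": "ACG", "H": "ACT", "D": "AGT", "B": "CGT",
}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def window_matches(window: str, pattern: str) -> bool:
    return len(window) == len(pattern) and all(
        w in IUPAC[p] for w, p in zip(window, pattern))


def enumerate_hits(seq: str, pattern: str, strands: str = "sense"):
    """Brute-force (offset, strand) list for an IUPAC pattern."""
    n = len(pattern)
    hits = [
        (i + 1, "sense")
        for i in range(len(seq) - n + 1)
        if window_matches(seq[i:i + n], pattern)
    ]
    if strands == "both":
        rc = revcomp(seq)
        for i in range(len(rc) - n + 1):
            if window_matches(rc[i:i + n], pattern):
                hits.append((len(seq) - i - n + 1, "antisense"))
    return sorted(hits)


def random_promoter(rng: np.random.Generator, length: int = 1000,
                    gc: float = 0.366) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


@pytest.fixture(scope="session")
def small_simulation():
    """A small simulated genome shared by read-only tests."""
    config = synth.SimulationConfig(seed=11, n_genes=40, genes_per_contig=8)
    genome, genes, truth = synth.simulate_genome(config)
    return config, genome, genes, truth
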