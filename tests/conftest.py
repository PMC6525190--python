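"""Shared fixtures: synthetic amplicon loci, donors, and independent
alignment-score oracles used to check the Gotoh implementation."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import hdrquant as hq

NEG = float("-inf")


def make_locus(seed: int = 42, length: int = 250, strand: str = "+") -> hq.AmpliconLocus:
    """Random amplicon with a protospacer+TGG PAM embedded mid-sequence."""
    rng = np.random.default_rng(seed)
    core = "".join(rng.choice(list("ACGT"), length))
    spacer = core[100:120]
    ref = core[:120] + "TGG" + core[123:]
    if strand == "-":
        ref = hq.revcomp(ref)
    return hq.locate_protospacer(ref, spacer, name=f"demo{seed}_{strand}")


def make_donor(locus: hq.AmpliconLocus, position: int = 12, pam_block=None,
               orientation: str = "forward") -> hq.DonorTemplate:
    ref_base = locus.reference[hq.ps_coord_to_ref(locus, position)]
    if locus.strand == "-":
        ref_base = hq.revcomp(ref_base)
    allele = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref_base]
    return hq.design_donor(locus, (position, allele), pam_block=pam_block,
                           orientation=orientation)


@pytest.fixture(scope="session")
def locus() -> hq.AmpliconLocus:
    return make_locus()


@pytest.fixture(scope="session")
def donor(locus) -> hq.DonorTemplate:
    return make_donor(locus)


@pytest.fixture(scope="session")
def donor_with_block(locus) -> hq.DonorTemplate:
    return make_donor(locus, pam_block="TTT")


# ---------------------------------------------------------------------------
# independent alignment-score oracles
# ---------------------------------------------------------------------------

def enumerated_best_score(a: str, b: str, sc: hq.Scoring) -> float:
    """Exhaustive enumeration of every global alignment path (tiny inputs
    only); the gold standard the recursive oracle is checked against."""
    best = [NEG]

    def rec(i: int, j: int, prev: str, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = sc.match if a[i] == b[j] else sc.mismatch
            rec(i + 1, j + 1, "M", score + s)
        if j < len(b):
            cost = sc.gap_extend if prev == "X" else sc.gap_open + sc.gap_extend
            rec(i, j + 1, "X", score + cost)
        if i < len(a):
            cost = sc.gap_extend if prev == "Y" else sc.gap_open + sc.gap_extend
            rec(i + 1, j, "Y", score + cost)

    rec(0, 0, "", 0.0)
    return best[0]


def oracle_score(a: str, b: str, sc: hq.Scoring) -> float:
    """Memoized suffix-recursion over (position, pending gap state); coded
    independently of the iterative three-matrix implementation."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = [NEG]
        if i < len(a) and j < len(b):
            s = sc.match if a[i] == b[j] else sc.mismatch
            options.append(s + f(i + 1, j + 1, "M"))
        if j < len(b):
            cost = sc.gap_extend if prev == "X" else sc.gap_open + sc.gap_extend
            options.append(cost + f(i, j + 1, "X"))
        if i < len(a):
            cost = sc.gap_extend if prev == "Y" else sc.gap_open + sc.gap_extend
            options.append(cost + f(i + 1, j, "Y"))
        return max(options)

    result = f(0, 0, "")
    f.cache_clear()
    return result


def random_sequence_pairs(n_pairs: int, max_len: int, seed: int):
    """Seeded random ACGT pairs with lengths 1..max_len (skewed to be
    related sequences half the time so gaps actually occur)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pairs = []
    while len(pairs) < n_pairs:
        la = int(rng.integers(1, max_len + 1))
        a = "".join(rng.choice(bases, la))
        if rng.random() < 0.5:
            # perturb a: substitutions/indels, keeping length within bounds
            b = list(a)
            for _ in range(int(rng.integers(1, 3))):
                op = rng.integers(0, 3)
                pos = int(rng.integers(0, max(1, len(b))))
                if op == 0 and b:
                    b[pos] = str(rng.choice(bases))
                elif op == 1 and len(b) < max_len:
                    b.insert(pos, str(rng.choice(bases)))
                elif op == 2 and len(b) > 1:
                    del b[pos]
            b = "".join(b)
        else:
            lb = int(rng.integers(1, max_len + 1))
            b = "".join(rng.choice(bases, lb))
        if a and b:
            pairs.append((a, b))
    return pairs
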