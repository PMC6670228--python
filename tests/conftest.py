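"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive everything from first principles (their
own codon table, IUPAC sets and complement map) so they stay independent of
the package code paths they check.
"""

from __future__ import annotations

import pytest

# --- independent standard genetic code (classic TCAG ordering) -------------

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_ORACLE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def oracle_translate(dna: str) -> str:
    return "".join(
        CODON_ORACLE[dna[i : i + 3]] for i in range(0, len(dna) - len(dna) % 3, 3)
    )


# --- independent IUPAC machinery -------------------------------------------

IUPAC_ORACLE = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "M": "AC",
    "K": "GT", "S": "CG", "W": "AT", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _plus_matches(query: str, seq: str, max_mm: int, require_pam: bool):
    L = len(query)
    out = []
    for i in range(len(seq) - L + 1):
        mm = sum(
            seq[i + j] not in IUPAC_ORACLE[query[j]] for j in range(L)
        )
        if mm > max_mm:
            continue
        pam = seq[i + L : i + L + 3]
        if require_pam and not (len(pam) == 3 and pam[1] == "G" and pam[2] == "G"):
            continue
        out.append((i, i + L, mm, i + L - 3))
    return out


def oracle_matches(query: str, seq: str, max_mm: int = 0, require_pam: bool = True):
    """Brute-force sliding-window matches on both strands.

    Returns a set of (start, end, strand, mismatches, cut_index) in coding
    coordinates.
    """
    n = len(seq)
    out = set()
    for start, end, mm, cut in _plus_matches(query, seq, max_mm, require_pam):
        out.add((start, end, "+", mm, cut))
    rc_seq = oracle_revcomp(seq)
    for p_start, p_end, mm, p_cut in _plus_matches(query, rc_seq, max_mm, require_pam):
        L = p_end - p_start
        out.add((n - p_end, n - p_start, "-", mm, n - p_cut))
    return out


def oracle_epitope_hits(protein: str, peptides: dict[str, str]):
    """All-window exhaustive 9-mer scan: set of (name, 1-based position)."""
    hits = set()
    for name, pep in peptides.items():
        for i in range(len(protein) - len(pep) + 1):
            if protein[i : i + len(pep)] == pep:
                hits.add((name, i + 1))
    return hits


def oracle_hairpin(s: str, min_loop: int) -> int:
    """Exhaustive triple loop over (i, j, stem length)."""
    best = 0
    n = len(s)
    for length in range(1, n // 2 + 1):
        for i in range(n - length + 1):
            for j in range(i + length + min_loop, n - length + 1):
                if s[j : j + length] == oracle_revcomp(s[i : i + length]):
                    best = max(best, length)
    return best


def oracle_cross_dimer(a: str, b: str) -> int:
    """Exhaustive antiparallel pairing scan over all start pairs."""
    best = 0
    for i0 in range(len(a)):
        for j0 in range(len(b) - 1, -1, -1):
            run = 0
            i, j = i0, j0
            while i < len(a) and j >= 0 and _COMP[a[i]] == b[j]:
                run += 1
                i += 1
                j -= 1
            best = max(best, run)
    return best


# --- fixtures ---------------------------------------------------------------

@pytest.fixture(scope="session")
def catalogue():
    from gliadkit.annotation import default_catalogue

    return default_catalogue()


@pytest.fixture(scope="session")
def alpha_catalogue(catalogue):
    return catalogue.subset("alpha")


@pytest.fixture(scope="session")
def gamma_catalogue(catalogue):
    return catalogue.subset("gamma")


@pytest.fixture(scope="session")
def small_alpha():
    """Small intact alpha family with generation plan."""
    from gliadkit.synthetic import default_alpha_spec, generate_family

    spec = default_alpha_spec(n_copies_total=20, pseudogene_fraction=0.0, seed=42)
    genes, plan = generate_family(spec, return_plan=True)
    return genes, plan


@pytest.fixture(scope="session")
def shipped_guides():
    from gliadkit.guides import load_guides

    return {g.name: g for g in load_guides()}
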