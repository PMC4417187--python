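"""Independent oracles used to validate the production implementations.

These deliberately share no code with the package: the repeat oracle
detects runs of equality at every fixed offset (rather than seeding on
shared k-mers), and the codon-bias oracle evaluates Wright's formula
family by family straight from Biopython's code tables.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable


def brute_force_direct_repeats(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal same-strand repeat pairs (pos1, pos2, length), sorted.

    For each offset d, a maximal pair at distance d is exactly a maximal
    run of positions i with seq[i] == seq[i+d].
    """
    a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    n = len(a)
    out: list[tuple[int, int, int]] = []
    for d in range(1, n):
        eq = (a[: n - d] == a[d:]).astype(np.int8)
        boundary = np.diff(np.concatenate(([0], eq, [0])))
        starts = np.flatnonzero(boundary == 1)
        ends = np.flatnonzero(boundary == -1)
        for s, e in zip(starts, ends):
            if e - s >= min_len:
                out.append((int(s), int(s + d), int(e - s)))
    return sorted(out)


def wright_nc_oracle(counts: dict[str, int], table_id: int = 1) -> float:
    """Wright's N_c straight from the per-family formula (no imputation paths).

    Assumes every multi-codon family has at least 2 counted codons and a
    positive homozygosity estimate, which the random tables used in the
    tests guarantee by construction.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    families: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        families.setdefault(aa, []).append(codon)
    f_by_k: dict[int, list[float]] = {}
    n_single = 0
    for codons in families.values():
        k = len(codons)
        if k == 1:
            n_single += 1
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        assert n >= 2, "oracle requires every family to have n >= 2"
        f_hat = (n * sum((c / n) ** 2 for c in ns) - 1) / (n - 1)
        assert f_hat > 0, "oracle requires positive homozygosity"
        f_by_k.setdefault(k, []).append(f_hat)
    nc = float(n_single)
    for k, fs in f_by_k.items():
        nc += len(fs) / (sum(fs) / len(fs))
    return min(nc, float(len(table.forward_table)))
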