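"""Independent brute-force oracles used by the test suite.

These re-derive expected results from first principles (explicit
enumeration, exact combinatorics) without calling the package's own
implementations, so agreement is a genuine cross-check.
"""

from __future__ import annotations

from math import comb

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}


def _wc(m_nt: str, t_nt: str) -> bool:
    return _COMP.get(m_nt) == t_nt


def naive_scan(
    target: str,
    mirna_seq: str,
    min_class: str = "6mer",
    max_bulge: int = 5,
    max_mismatches: int = 3,
    bulge_range: tuple[int, int] = (1, 5),
    min_paired: int = 6,
    min_run: int = 4,
) -> list[dict]:
    """Enumerate every offset and bulge geometry of a linear target.

    Returns one record per seed-matched offset with the best-scoring
    3' geometry (max paired, then min mismatches, min bulge, 5'-most
    loop) and the architecture implied by the TDMD thresholds.
    """
    n = len(mirna_seq)
    out = []
    for q in range(6, len(target)):
        if not all(_wc(mirna_seq[k - 1], target[q - (k - 1)]) for k in range(2, 8)):
            continue
        m8 = q - 7 >= 0 and _wc(mirna_seq[7], target[q - 7])
        t1a = target[q] == "A"
        if m8 and t1a:
            cls = "8mer"
        elif m8:
            cls = "7mer-m8"
        elif t1a:
            cls = "7mer-A1"
        else:
            cls = "6mer"
        if _RANK[cls] < _RANK[min_class]:
            continue
        geometries = []
        for b in range(0, max_bulge + 1):
            for j in [8] if b == 0 else [8, 9, 10, 11]:
                mask = []
                for k in range(9, n + 1):
                    t = q - (k - 1) - (b if k > j else 0)
                    mask.append(0 <= t < len(target) and _wc(mirna_seq[k - 1], target[t]))
                tail = mask[4:]  # positions 13..n
                paired = sum(tail)
                mism = sum(1 for ok in mask if not ok)
                run = best = 0
                for ok in tail:
                    run = run + 1 if ok else 0
                    best = max(best, run)
                geometries.append(
                    {"paired": paired, "mism": mism, "bulge": b, "j": j, "run": best}
                )
        top = min(geometries, key=lambda g: (-g["paired"], g["mism"], g["bulge"], g["j"]))
        if (
            _RANK[cls] >= _RANK["7mer-m8"]
            and top["bulge"] == 0
            and top["mism"] == 0
            and top["paired"] == n - 12
        ):
            arch = "slicing"
        elif (
            _RANK[cls] >= _RANK["7mer-A1"]
            and bulge_range[0] <= top["bulge"] <= bulge_range[1]
            and top["paired"] >= min_paired
            and top["run"] >= min_run
            and top["mism"] <= max_mismatches
        ):
            arch = "TDMD-like"
        else:
            arch = "canonical"
        out.append(
            {
                "offset": q,
                "seed_class": cls,
                "paired_3p": top["paired"],
                "mismatches_3p": top["mism"],
                "bulge_len": top["bulge"],
                "paired_run_3p": top["run"],
                "architecture": arch,
            }
        )
    return out


def fisher_greater_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p for [[a, b], [c, d]] by tail summation.

    Sums hypergeometric probabilities over all tables with the observed
    margins whose first cell is >= a, using exact integer binomials.
    """
    n1, n2, k = a + b, c + d, a + c
    denom = comb(n1 + n2, k)
    lo, hi = max(0, k - n2), min(n1, k)
    total = 0
    for x in range(a, hi + 1):
        total += comb(n1, x) * comb(n2, k - x)
    return total / denom


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: sum of all tables as or less probable."""
    n1, n2, k = a + b, c + d, a + c
    denom = comb(n1 + n2, k)
    lo, hi = max(0, k - n2), min(n1, k)
    probs = {x: comb(n1, x) * comb(n2, k - x) for x in range(lo, hi + 1)}
    obs = probs[a]
    # integer arithmetic: no floating tolerance needed for the comparison
    total = sum(p for p in probs.values() if p <= obs)
    return total / denom
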