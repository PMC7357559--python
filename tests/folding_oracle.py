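"""Independent folding oracle: exhaustive enumeration of every non-crossing
secondary structure (canonical + GU pairs, hairpin loops >= 3 nt), each
scored with the thermodynamic evaluator.  The search is independent of the
dynamic program under test; only the energy rules are shared, as required
for an exact comparison."""
from functools import lru_cache

import RNA

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


def enumerate_structures(seq: str) -> list[str]:
    """All non-crossing structures of a short RNA as dot-bracket strings."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def structs(i: int, j: int):
        if j - i < 0:
            return [()]
        out = list(structs(i + 1, j))  # i unpaired
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in PAIRS:
                for inner in structs(i + 1, k - 1):
                    for outer in structs(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return out

    result = []
    for pairs in structs(0, n - 1):
        db = ["."] * n
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        result.append("".join(db))
    structs.cache_clear()
    return result


def mfe_by_enumeration(seq: str) -> float:
    """Minimum energy over all enumerated structures (kcal/mol)."""
    fc = RNA.fold_compound(seq)
    return min(fc.eval_structure(db) for db in enumerate_structures(seq))
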