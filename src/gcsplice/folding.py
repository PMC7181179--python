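"""Minimum-free-energy folding backends for the start-codon window.

Two backends are exposed:

``vienna``
    Calls the ViennaRNA ``RNAfold`` executable (37 C, RNA parameters) and
    reports its MFE in kcal/mol.  This is the default when the executable
    is on PATH.

``basic``
    A coarse bundled model: Nussinov-style dynamic programming that
    maximizes stacking-weighted base pairs (GC -3, AU -2, GU -1 kcal/mol,
    minimum hairpin loop of 3 nt).  Its absolute energies are not
    comparable with thermodynamic MFEs, but signs and rankings of clearly
    structured versus unstructured windows agree.

Absolute dG values are backend-dependent; analyses downstream only rely on
sign and relative ordering.
"""

from __future__ import annotations

import shutil
import subprocess

__all__ = ["mfe", "available_backends", "DEFAULT_BACKEND"]

_PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "T"): -2.0, ("T", "A"): -2.0,
    ("G", "T"): -1.0, ("T", "G"): -1.0,
}
_MIN_LOOP = 3


def _mfe_vienna(seq: str) -> float:
    rna = seq.upper().replace("T", "U")
    proc = subprocess.run(
        ["RNAfold", "--noPS"],
        input=f">w\n{rna}\n",
        capture_output=True,
        text=True,
        check=True,
    )
    last = proc.stdout.strip().splitlines()[-1]
    # e.g. "((((....)))) ( -5.20)"
    energy = last[last.rindex("(") + 1 : last.rindex(")")]
    return float(energy)


def _mfe_basic(seq: str) -> float:
    s = seq.upper()
    n = len(s)
    best = [[0.0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            e = best[i][j - 1]
            for k in range(i, j - _MIN_LOOP):
                pair = _PAIR_ENERGY.get((s[k], s[j]))
                if pair is None:
                    continue
                left = best[i][k - 1] if k > i else 0.0
                inner = best[k + 1][j - 1]
                e = min(e, left + pair + inner)
            best[i][j] = e
    return best[0][n - 1] if n else 0.0


_BACKENDS = {"vienna": _mfe_vienna, "basic": _mfe_basic}


def available_backends() -> list[str]:
    out = ["basic"]
    if shutil.which("RNAfold"):
        out.insert(0, "vienna")
    return out


DEFAULT_BACKEND = "vienna" if shutil.which("RNAfold") else "basic"


def mfe(seq: str, backend: str | None = None) -> float:
    """Minimum free energy (kcal/mol, <= 0) of a nucleotide sequence."""
    if not seq:
        raise ValueError("empty sequence")
    name = backend or DEFAULT_BACKEND
    try:
        fn = _BACKENDS[name]
    except KeyError:
        raise ValueError(f"unknown folding backend {name!r}; choose from {sorted(_BACKENDS)}")
    return min(0.0, fn(seq))
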