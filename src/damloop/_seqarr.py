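"""Byte-array DNA utilities shared by the read simulator and the matcher."""

from __future__ import annotations

import numpy as np

# ASCII byte -> 2-bit code; 255 marks anything that is not A/C/G/T
CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    CODE[_b] = _i
DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    COMP[_a] = _b


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def u8_to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_rows(mat: np.ndarray, lens: np.ndarray, pad: int = 0) -> np.ndarray:
    """Reverse-complement each row of a padded read matrix in place-order.

    Row ``i`` holds ``lens[i]`` valid bases left-aligned; the result is the
    reverse complement, left-aligned again.
    """
    n, w = mat.shape
    out = np.full_like(mat, pad)
    full = lens == w
    if full.any():
        out[full] = COMP[mat[full][:, ::-1]]
    # group remaining rows by length so each group reverses with a slice
    for l in np.unique(lens[~full]):
        rows = np.flatnonzero(lens == l)
        li = int(l)
        out[rows[:, None], np.arange(li)[None, :]] = COMP[mat[rows][:, li - 1 :: -1]]
    return out


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-k window of a 2-bit code array into uint64 keys.

    Returns (keys, valid) where ``valid`` flags windows free of non-ACGT
    bases.  ``codes`` is the output of ``CODE[bytes]``.
    """
    if len(codes) < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    n = len(codes) - k + 1
    clean = np.where(codes == 255, 0, codes).astype(np.uint64)
    keys = np.zeros(n, dtype=np.uint64)
    four = np.uint64(4)
    for j in range(k):  # Horner packing, one vector op per base
        keys = keys * four + clean[j : j + n]
    bad = np.concatenate([[0], np.cumsum(codes == 255)])
    valid = (bad[k:] - bad[:-k]) == 0
    keys[~valid] = np.uint64(0)
    return keys, valid
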