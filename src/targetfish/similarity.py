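"""166-key structural fingerprints and Dice-similarity ranking.

Fingerprints are the 166 standard structural keys (RDKit emits them as a
167-bit vector whose bit 0 is unused; we keep keys 1..166). Similarity is
the Dice coefficient 2c/(a+b) over on-bit counts. Unparseable or
multi-component structures yield ``None`` — unavailability is a first-class
return, never an exception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

logger = logging.getLogger(__name__)

FP_LENGTH = 166
# 166 bits + 2 padding zero bits = 168 bits = 21 bytes = 42 hex characters
_HEX_LENGTH = 42


class Fingerprint:
    """Fixed-length 166-bit binary key vector with a cached popcount."""

    __slots__ = ("_bits", "_popcount")

    def __init__(self, bits) -> None:
        arr = np.asarray(bits, dtype=np.uint8)
        if arr.shape != (FP_LENGTH,):
            raise ValueError(f"fingerprint must have length {FP_LENGTH}, got {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        arr.setflags(write=False)
        self._bits = arr
        self._popcount = int(arr.sum())

    @property
    def bits(self) -> np.ndarray:
        return self._bits

    @property
    def popcount(self) -> int:
        return self._popcount

    def __eq__(self, other) -> bool:
        if not isinstance(other, Fingerprint):
            return NotImplemented
        return bool(np.array_equal(self._bits, other._bits))

    def __hash__(self) -> int:
        return hash(self._bits.tobytes())

    def __repr__(self) -> str:
        return f"Fingerprint(popcount={self._popcount})"

    def to_hex(self) -> str:
        """42-character hexadecimal encoding: 166 bits + 2 padding zeros."""
        padded = np.concatenate([self._bits, np.zeros(2, dtype=np.uint8)])
        return np.packbits(padded).tobytes().hex()

    @classmethod
    def from_hex(cls, hexstring: str) -> "Fingerprint":
        if len(hexstring) != _HEX_LENGTH:
            raise ValueError(f"expected {_HEX_LENGTH} hex characters, got {len(hexstring)}")
        raw = np.frombuffer(bytes.fromhex(hexstring), dtype=np.uint8)
        bits = np.unpackbits(raw)[:FP_LENGTH]
        return cls(bits)


def compute_fingerprint(smiles: str) -> Optional[Fingerprint]:
    """Compute the 166-key fingerprint of a single-component SMILES.

    Returns ``None`` (the unavailable marker) for unparseable strings and
    for multi-component (dot-disconnected) structures such as mixtures;
    never raises for bad input.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    if len(Chem.GetMolFrags(mol)) > 1:
        return None
    keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
    bits = np.zeros(167, dtype=np.uint8)
    bits[list(keys.GetOnBits())] = 1
    return Fingerprint(bits[1:])


def dice_score(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Dice similarity 2c/(a+b); 0.0 when both fingerprints are empty."""
    a = fp_a.popcount
    b = fp_b.popcount
    if a + b == 0:
        return 0.0
    c = int(np.dot(fp_a.bits.astype(np.int64), fp_b.bits.astype(np.int64)))
    return 2.0 * c / (a + b)


@dataclass(frozen=True)
class RankedHit:
    """One database molecule with its similarity score and 1-based rank."""

    molecule_id: str
    score: float
    rank: int


def rank_database(
    query_fp: Fingerprint,
    db: Mapping[str, Fingerprint] | Iterable[tuple[str, Fingerprint]],
) -> list[RankedHit]:
    """Score every database molecule against the query and rank them.

    Sorted by descending Dice score; ties broken by ascending molecule id so
    rankings are deterministic.
    """
    items = list(db.items()) if isinstance(db, Mapping) else list(db)
    if not items:
        return []
    ids = [mid for mid, _ in items]
    matrix = np.stack([fp.bits for _, fp in items]).astype(np.int64)
    pops = matrix.sum(axis=1)
    shared = matrix @ query_fp.bits.astype(np.int64)
    denom = pops + query_fp.popcount
    with np.errstate(invalid="ignore"):
        scores = np.where(denom > 0, 2.0 * shared / np.maximum(denom, 1), 0.0)
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return [
        RankedHit(molecule_id=ids[i], score=float(scores[i]), rank=pos + 1)
        for pos, i in enumerate(order)
    ]


def top_k(ranked: list[RankedHit], k: int) -> list[RankedHit]:
    """First min(k, len(ranked)) hits; a prefix of the full ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ranked[:k]


# -- structure and cache I/O -------------------------------------------------

def read_smiles_file(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>smiles`` file into a dict."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            out[parts[0].strip()] = parts[1].strip()
    return out


def read_sdf_file(path: str | Path) -> dict[str, str]:
    """Read an SDF, keyed by the molecule name (or ``molecule_id`` property)."""
    from rdkit import Chem

    out: dict[str, str] = {}
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for mol in supplier:
        if mol is None:
            continue
        if mol.HasProp("molecule_id"):
            mid = mol.GetProp("molecule_id")
        else:
            mid = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if mid:
            out[mid] = Chem.MolToSmiles(mol)
    return out


def read_structures(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if path.suffix.lower() == ".sdf":
        return read_sdf_file(path)
    return read_smiles_file(path)


def write_fingerprint_cache(path: str | Path, fps: Mapping[str, Fingerprint]) -> None:
    """Serialize fingerprints as ``id<TAB>hex`` lines (42 hex chars each)."""
    with open(path, "w") as fh:
        for mid in sorted(fps):
            fh.write(f"{mid}\t{fps[mid].to_hex()}\n")


def read_fingerprint_cache(path: str | Path) -> dict[str, Fingerprint]:
    out: dict[str, Fingerprint] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            mid, hexstr = line.split("\t")
            out[mid] = Fingerprint.from_hex(hexstr)
    return out
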