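"""2D fingerprint similarity: MACCS / ECFP4 Tanimoto cascade.

The first screening stage compares every drug against every cell-active
compound with two complementary bit fingerprints — the 166 MACCS structural
keys and the radius-2 circular (Morgan/ECFP4) fingerprint folded to a fixed
length — and retains pairs whose Tanimoto coefficients clear both
thresholds (defaults 0.8 for MACCS and 0.3 for ECFP4, combined with AND).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .curation import CompoundRecord
from .errors import IncompatibleFingerprintError

MACCS_LENGTH = 166
DEFAULT_ECFP4_LENGTH = 2048


class FingerprintKind(str, Enum):
    MACCS = "MACCS"
    ECFP4 = "ECFP4"


@dataclass(frozen=True)
class Fingerprint:
    """A bit fingerprint as a set of on-bit indices in ``[0, length)``."""

    kind: FingerprintKind
    bits: frozenset[int]
    length: int


@dataclass(frozen=True)
class Pair2DScore:
    """Tanimoto scores for one (drug, active) pair; symmetric in the pair."""

    drug_id: str
    active_id: str
    tc_maccs: float
    tc_ecfp4: float


def fingerprint(
    compound: CompoundRecord,
    kind: FingerprintKind,
    ecfp4_length: int = DEFAULT_ECFP4_LENGTH,
) -> Fingerprint:
    """Compute a deterministic bit fingerprint for a standardized compound.

    MACCS uses the public 166-key SMARTS dictionary (the toolkit's unused
    leading bit is dropped, so indices run 0..165). ECFP4 is the circular
    fingerprint of bond radius 2 folded to ``ecfp4_length`` bits; folding
    collisions are inherent and accepted.
    """
    mol = compound.structure
    if kind is FingerprintKind.MACCS:
        bv = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 never set
        bits = frozenset(i - 1 for i in bv.GetOnBits())
        return Fingerprint(kind=kind, bits=bits, length=MACCS_LENGTH)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ecfp4_length)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(kind=kind, bits=frozenset(bv.GetOnBits()), length=ecfp4_length)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| between two fingerprints.

    Two empty bit sets count as identical (Tc = 1); empty against non-empty
    gives 0. In practice the curation MW floor makes empty fingerprints
    unreachable.

    Raises
    ------
    IncompatibleFingerprintError
        If the kinds or lengths differ.
    """
    if a.kind != b.kind or a.length != b.length:
        raise IncompatibleFingerprintError(
            f"cannot compare {a.kind.value}/{a.length} with {b.kind.value}/{b.length}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


def all_against_all_2d(
    drugs: Sequence[CompoundRecord],
    actives: Sequence[CompoundRecord],
    ecfp4_length: int = DEFAULT_ECFP4_LENGTH,
) -> list[Pair2DScore]:
    """Score every (drug, active) pair with both fingerprints.

    Returns exactly ``len(drugs) * len(actives)`` pair scores, in
    drug-major order.
    """
    d_maccs = [fingerprint(d, FingerprintKind.MACCS) for d in drugs]
    d_ecfp = [fingerprint(d, FingerprintKind.ECFP4, ecfp4_length) for d in drugs]
    a_maccs = [fingerprint(a, FingerprintKind.MACCS) for a in actives]
    a_ecfp = [fingerprint(a, FingerprintKind.ECFP4, ecfp4_length) for a in actives]
    out = []
    for i, d in enumerate(drugs):
        for j, a in enumerate(actives):
            out.append(
                Pair2DScore(
                    drug_id=d.compound_id,
                    active_id=a.compound_id,
                    tc_maccs=tanimoto(d_maccs[i], a_maccs[j]),
                    tc_ecfp4=tanimoto(d_ecfp[i], a_ecfp[j]),
                )
            )
    return out


def cascade_filter_2d(
    pairs: Sequence[Pair2DScore],
    t_maccs: float = 0.8,
    t_ecfp4: float = 0.3,
) -> list[Pair2DScore]:
    """Retain pairs with tc_maccs >= t_maccs AND tc_ecfp4 >= t_ecfp4.

    Both boundaries are inclusive ("equal to or higher than").
    """
    return [p for p in pairs if p.tc_maccs >= t_maccs and p.tc_ecfp4 >= t_ecfp4]
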