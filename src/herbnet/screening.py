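"""Oral-bioavailability screening with Veber's rule.

A compound is predicted orally bioavailable when it has at most 10 rotatable
bonds and a topological polar surface area of at most 140 square angstroms;
both boundaries are inclusive.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Tuple

from .data_model import CompoundRecord, ScreenReport
from .errors import InvalidCompoundError

MAX_ROTATABLE_BONDS = 10
MAX_TPSA = 140.0


def veber_pass(rotatable_bonds: int, tpsa: float) -> bool:
    """True iff rotatable_bonds <= 10 and TPSA <= 140 (boundaries pass)."""
    _check_descriptors(rotatable_bonds, tpsa)
    return rotatable_bonds <= MAX_ROTATABLE_BONDS and tpsa <= MAX_TPSA


def failing_criterion(rotatable_bonds: int, tpsa: float) -> str:
    """Which rule the compound breaks: "none", "bonds", "tpsa" or "both"."""
    _check_descriptors(rotatable_bonds, tpsa)
    bonds_fail = rotatable_bonds > MAX_ROTATABLE_BONDS
    tpsa_fail = tpsa > MAX_TPSA
    if bonds_fail and tpsa_fail:
        return "both"
    if bonds_fail:
        return "bonds"
    if tpsa_fail:
        return "tpsa"
    return "none"


def _check_descriptors(rotatable_bonds, tpsa) -> None:
    if rotatable_bonds is None or tpsa is None:
        raise InvalidCompoundError("missing descriptor (rotatable_bonds or tpsa)")
    if rotatable_bonds < 0 or tpsa < 0 or not math.isfinite(float(tpsa)):
        raise InvalidCompoundError(
            f"descriptors must be non-negative and finite, got "
            f"rotatable_bonds={rotatable_bonds}, tpsa={tpsa}"
        )


def screen_compounds(
    records: Iterable[CompoundRecord],
) -> Tuple[List[CompoundRecord], ScreenReport]:
    """Filter records through Veber's rule, preserving input order.

    Records with missing or invalid descriptors abort the screen with an
    error listing the offending compound ids; they are never silently
    dropped or passed.
    """
    records = list(records)
    bad = [
        r.compound_id
        for r in records
        if r.rotatable_bonds is None
        or r.tpsa is None
        or r.rotatable_bonds < 0
        or r.tpsa < 0
    ]
    if bad:
        raise InvalidCompoundError(
            f"invalid or missing descriptors for: {', '.join(bad)}", compound_ids=bad
        )
    flags = {
        r.compound_id: failing_criterion(r.rotatable_bonds, r.tpsa) for r in records
    }
    passing = [r for r in records if flags[r.compound_id] == "none"]
    report = ScreenReport(
        n_input=len(records), n_pass=len(passing), failing_criterion=flags
    )
    return passing, report
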