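"""Crossover-breakpoint detection in genotyped recombinants.

Each selected recombinant is expected to show exactly one transition between
a heterozygous and a homozygous block of marker genotypes along the
interval; the crossover is localized to the pair of informative markers
bracketing that transition.  Detection is a deterministic run-length
segmentation: NOCALLs are ignored, runs of identical states are formed, and
short discordant runs (below ``min_flank`` markers) are absorbed as
genotyping errors.  Samples without a clean single transition are retained
with a diagnostic status so cohort success rates can be recomputed from the
result table alone.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .genotyping import HET, HOM_ALT, HOM_REF, NOCALL, STATE_NAMES, MarkerTable

log = logging.getLogger(__name__)

OK = "OK"
NO_TRANSITION = "NO_TRANSITION"
MULTIPLE_TRANSITIONS = "MULTIPLE_TRANSITIONS"
INSUFFICIENT_MARKERS = "INSUFFICIENT_MARKERS"

STATUSES = (OK, NO_TRANSITION, MULTIPLE_TRANSITIONS, INSUFFICIENT_MARKERS)


@dataclass(frozen=True)
class CrossoverCall:
    sample_id: str
    status: str
    left_pos: int | None = None  # last informative marker before the breakpoint
    right_pos: int | None = None  # first informative marker after it
    direction: str | None = None  # e.g. "HET->HOM_ALT"

    @property
    def midpoint(self) -> float | None:
        if self.status != OK:
            return None
        return (self.left_pos + self.right_pos) / 2.0


@dataclass
class CohortResult:
    calls: list[CrossoverCall]

    @property
    def n_attempted(self) -> int:
        return len(self.calls)

    @property
    def n_ok(self) -> int:
        return sum(1 for c in self.calls if c.status == OK)

    @property
    def success_rate_percent(self) -> float:
        if self.n_attempted == 0:
            return 0.0
        return 100.0 * self.n_ok / self.n_attempted

    @property
    def ok_calls(self) -> list[CrossoverCall]:
        return [c for c in self.calls if c.status == OK]

    def status_counts(self) -> Counter:
        return Counter(c.status for c in self.calls)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in self.calls],
                "status": [c.status for c in self.calls],
                "left_pos": [c.left_pos for c in self.calls],
                "right_pos": [c.right_pos for c in self.calls],
                "midpoint": [c.midpoint for c in self.calls],
                "direction": [c.direction for c in self.calls],
            }
        )


def _runs(states: np.ndarray) -> list[list]:
    """Run-length encode: list of [state, count]."""
    runs: list[list] = []
    for s in states:
        if runs and runs[-1][0] == s:
            runs[-1][1] += 1
        else:
            runs.append([int(s), 1])
    return runs


def _absorb_short_runs(runs: list[list], min_flank: int) -> list[list]:
    """Merge runs shorter than min_flank into their neighbors.

    A short run flanked by two runs of the same state is treated as a burst
    of genotyping errors inside that state; a short run at either edge is
    merged into its single neighbor.  A short run between two *different*
    states is left in place (it then triggers MULTIPLE_TRANSITIONS).
    """
    runs = [list(r) for r in runs]
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (state, count) in enumerate(runs):
            if count >= min_flank:
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i + 1 < len(runs) else None
            if left is not None and right is not None:
                if left[0] != right[0]:
                    continue
                merged = [left[0], left[1] + count + right[1]]
                runs[i - 1 : i + 2] = [merged]
            elif right is not None:
                runs[i : i + 2] = [[right[0], right[1] + count]]
            elif left is not None:
                runs[i - 1 : i + 1] = [[left[0], left[1] + count]]
            else:
                break
            changed = True
            break
    return runs


def _direction(a: int, b: int) -> str:
    return f"{STATE_NAMES[a]}->{STATE_NAMES[b]}"


def detect_transition(
    genotypes: np.ndarray,
    positions: np.ndarray,
    min_flank: int = 2,
    sample_id: str = "",
) -> CrossoverCall:
    """Locate the single HET<->HOM genotype transition in one sample.

    ``genotypes`` is the ordered state vector over markers at ``positions``.
    Requires at least ``min_flank`` concordant informative markers on each
    side of the breakpoint.
    """
    if min_flank < 1:
        raise InputError("min_flank must be >= 1")
    genotypes = np.asarray(genotypes)
    positions = np.asarray(positions)
    if genotypes.size == 0:
        raise InputError(f"sample {sample_id!r}: empty genotype vector")
    if genotypes.shape != positions.shape:
        raise InputError("genotypes/positions length mismatch")

    informative = genotypes != NOCALL
    idx = np.flatnonzero(informative)
    if idx.size < 2 * min_flank:
        return CrossoverCall(sample_id, INSUFFICIENT_MARKERS)

    states = genotypes[idx]
    runs = _absorb_short_runs(_runs(states), min_flank)

    if len(runs) == 1:
        return CrossoverCall(sample_id, NO_TRANSITION)
    if len(runs) > 2:
        return CrossoverCall(sample_id, MULTIPLE_TRANSITIONS)

    (s1, n1), (s2, n2) = runs
    if n1 < min_flank or n2 < min_flank:
        return CrossoverCall(sample_id, INSUFFICIENT_MARKERS)
    if {s1, s2} == {HOM_REF, HOM_ALT}:
        # adjacent opposite homozygotes would need two crossovers between
        # consecutive markers — flagged, not resolved
        log.warning("sample %s: HOM_REF<->HOM_ALT adjacency; flagged as multiple transitions", sample_id)
        return CrossoverCall(sample_id, MULTIPLE_TRANSITIONS)
    if HET not in (s1, s2):
        return CrossoverCall(sample_id, MULTIPLE_TRANSITIONS)

    left_informative = idx[n1 - 1]
    right_informative = idx[n1]
    return CrossoverCall(
        sample_id,
        OK,
        left_pos=int(positions[left_informative]),
        right_pos=int(positions[right_informative]),
        direction=_direction(s1, s2),
    )


def call_cohort(
    genotype_matrix: np.ndarray,
    markers: MarkerTable,
    min_flank: int = 2,
    sample_ids: list[str] | None = None,
) -> CohortResult:
    """Run transition detection over every sample of a genotype matrix."""
    geno = np.asarray(genotype_matrix)
    if geno.ndim != 2 or geno.shape[0] == 0:
        raise InputError("genotype matrix must be non-empty and 2-dimensional")
    if geno.shape[1] != len(markers):
        raise InputError(f"genotype matrix has {geno.shape[1]} markers, table has {len(markers)}")
    ids = sample_ids or [f"sample_{i + 1:04d}" for i in range(geno.shape[0])]
    positions = markers.positions
    calls = [detect_transition(geno[i], positions, min_flank, ids[i]) for i in range(geno.shape[0])]
    result = CohortResult(calls)
    log.info(
        "call_cohort: %d/%d OK (%.1f%%); %s",
        result.n_ok,
        result.n_attempted,
        result.success_rate_percent,
        dict(result.status_counts()),
    )
    return result


# Default reporter layout: the reference (reporter-carrying) chromosome has
# the green reporter upstream of the interval and the red reporter
# downstream, so a recombinant losing the downstream half of the
# heterozygous block is a green-only (G-/--) seed and vice versa.
DEFAULT_REPORTER_LAYOUT = {
    "HET->HOM_ALT": "G-/--",
    "HOM_ALT->HET": "--/-R",
}


def classify_recombinant(
    call: CrossoverCall,
    reporter_layout: dict[str, str] | None = None,
    recorded_class: str | None = None,
) -> tuple[str, bool]:
    """Map a crossover direction to the fluorescent seed class it implies.

    Returns (expected class, mismatch flag); the flag is set when a recorded
    selection class is supplied and disagrees with the expectation.
    """
    if call.status != OK:
        raise InputError(f"sample {call.sample_id!r}: cannot classify a {call.status} call")
    layout = reporter_layout or DEFAULT_REPORTER_LAYOUT
    if call.direction not in layout:
        raise InputError(f"direction {call.direction!r} not present in reporter layout")
    expected = layout[call.direction]
    mismatch = recorded_class is not None and recorded_class != expected
    if mismatch:
        log.warning(
            "sample %s: recorded class %s disagrees with expected %s",
            call.sample_id,
            recorded_class,
            expected,
        )
    return expected, mismatch


def calls_from_truth(truth) -> CohortResult:
    """Idealized calls straight from simulation truth (bracketing markers).

    Bypasses sequencing noise and genotyping: each true crossover position is
    bracketed by its flanking markers.  Useful as an oracle and for
    section-level power studies where only positions matter.
    """
    positions = truth.markers.positions
    calls = []
    from .simulate import HET_TO_HOM

    for i, co in enumerate(truth.co_positions):
        j = int(np.searchsorted(positions, co))
        j = min(max(j, 1), len(positions) - 1)
        direction = "HET->HOM_ALT" if truth.orientations[i] == HET_TO_HOM else "HOM_ALT->HET"
        calls.append(
            CrossoverCall(
                truth.sample_ids[i] if truth.sample_ids else f"rec_{i + 1:04d}",
                OK,
                left_pos=int(positions[j - 1]),
                right_pos=int(positions[j]),
                direction=direction,
            )
        )
    return CohortResult(calls)
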