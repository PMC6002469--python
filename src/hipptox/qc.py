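"""Pre-analysis quality control.

Two procedures: the autofluorescence foreground-to-background ratio
(FBR) statistic with its one-third-of-positive-control acceptance
threshold, and the viability-plate CoV-based well-rejection procedure
(background subtraction, greedy dropping of high-variance wells, a
low-signal exemption, and the six-passing-concentrations rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import WellRecord, WellRole

__all__ = [
    "FBRResult",
    "ViabilityQCReport",
    "compute_fbr",
    "median_fbr",
    "fbr_acceptance",
    "viability_qc",
]

COV_LIMIT = 30.0  # % — groups above this get wells dropped
MAX_DROPS = 2
LOW_SIGNAL_FRACTION = 0.20  # treated median below 20% of control: CoV exempt
MIN_PASSING_CONCENTRATIONS = 6


@dataclass(frozen=True)
class FBRResult:
    chemical_id: str
    channel: str
    fbr: float  # log2 units, median across replicates
    threshold: float
    passed: bool


def compute_fbr(foreground, background) -> float:
    """log2 of the 99.9th-percentile foreground over the median background."""
    foreground = np.asarray(foreground, dtype=float)
    background = np.asarray(background, dtype=float)
    if foreground.size < 1000 or background.size < 1000:
        raise ValueError("need >= 1000 pixels per region")
    med_back = float(np.median(background))
    if med_back <= 0:
        raise ValueError("degenerate image: background median <= 0")
    return float(np.log2(np.percentile(foreground, 99.9) / med_back))


def median_fbr(replicate_fbrs) -> float:
    """Reported per-(chemical, channel) FBR: median over replicate images."""
    return float(np.median(np.asarray(replicate_fbrs, dtype=float)))


def fbr_acceptance(
    chemical_fbr: float,
    positive_control_fbr: float,
    chemical_id: str = "",
    channel: str = "",
) -> FBRResult:
    """Pass iff the chemical's FBR is at most 1/3 of the positive control's.

    The threshold is "maximally acceptable", so a value exactly at the
    threshold passes.
    """
    if positive_control_fbr <= 0:
        raise ValueError("positive-control FBR must be > 0")
    threshold = positive_control_fbr / 3.0
    return FBRResult(
        chemical_id=chemical_id,
        channel=channel,
        fbr=float(chemical_fbr),
        threshold=threshold,
        passed=chemical_fbr <= threshold,
    )


# ---------------------------------------------------------------------------
# viability plate QC


@dataclass
class ConcentrationQC:
    concentration: float
    retained_wells: list[str]
    dropped_wells: list[str]
    median_signal: float
    cov_percent: float
    cov_exemption: bool
    passed: bool


@dataclass
class ViabilityQCReport:
    chemical_id: str
    control: ConcentrationQC | None = None
    per_concentration: list[ConcentrationQC] = field(default_factory=list)
    n_passing_concentrations: int = 0
    verdict: str = "accept"  # or "repeat_required"


def _cov_percent(values: np.ndarray) -> float:
    if len(values) < 2 or np.mean(values) == 0:
        return 0.0
    return 100.0 * float(np.std(values, ddof=1) / np.mean(values))


def _greedy_drop(
    well_ids: list[str], values: np.ndarray, max_drops: int = MAX_DROPS
) -> tuple[list[str], list[str], np.ndarray]:
    """Drop up to ``max_drops`` wells, each time the one whose removal
    most reduces the CoV, stopping once CoV < 30%."""
    keep = list(range(len(values)))
    dropped: list[int] = []
    while len(dropped) < max_drops and _cov_percent(values[keep]) > COV_LIMIT:
        best_i, best_cov = None, np.inf
        for i in keep:
            rest = [j for j in keep if j != i]
            c = _cov_percent(values[rest])
            if c < best_cov:
                best_cov, best_i = c, i
        if best_i is None:
            break
        keep.remove(best_i)
        dropped.append(best_i)
    return (
        [well_ids[i] for i in keep],
        [well_ids[i] for i in dropped],
        values[keep],
    )


def viability_qc(
    plate: list[WellRecord], feature_id: str = "viability"
) -> dict[str, ViabilityQCReport]:
    """Run the viability-plate QC for every chemical on the plate.

    Steps: (1) subtract the mean of the no-cell control wells from every
    well; (2) per chemical, clean the solvent-control group by greedy
    CoV-driven well dropping (at most two drops) and take the median of
    the survivors as the control viability; (3) repeat per treated
    concentration, except that a treated group whose median is below 20%
    of the control median keeps its wells regardless of CoV; (4) at most
    one failing concentration is tolerated — with fewer than six passing
    concentrations the chemical's data must be re-collected.
    """
    rows = [r for r in plate if r.feature_id == feature_id]
    no_cell = [r.value for r in rows if r.role is WellRole.NO_CELL_CONTROL]
    if not no_cell:
        raise ValueError("no-cell control wells missing from the plate")
    background = float(np.mean(no_cell))

    by_chem: dict[str, list[WellRecord]] = {}
    for r in rows:
        if r.role in (WellRole.TREATMENT, WellRole.SOLVENT_CONTROL):
            by_chem.setdefault(r.chemical_id, []).append(r)

    reports: dict[str, ViabilityQCReport] = {}
    for chem, recs in sorted(by_chem.items()):
        report = ViabilityQCReport(chemical_id=chem)
        controls = sorted(
            (r for r in recs if r.role is WellRole.SOLVENT_CONTROL),
            key=lambda r: r.well_id,
        )
        ids = [r.well_id for r in controls]
        vals = np.array([r.value - background for r in controls])
        kept, dropped, kept_vals = _greedy_drop(ids, vals)
        control_median = float(np.median(kept_vals))
        report.control = ConcentrationQC(
            concentration=0.0,
            retained_wells=kept,
            dropped_wells=dropped,
            median_signal=control_median,
            cov_percent=_cov_percent(kept_vals),
            cov_exemption=False,
            passed=_cov_percent(kept_vals) < COV_LIMIT,
        )
        treated: dict[float, list[WellRecord]] = {}
        for r in recs:
            if r.role is WellRole.TREATMENT:
                treated.setdefault(r.concentration, []).append(r)
        n_pass = 0
        for x in sorted(treated, reverse=True):
            group = sorted(treated[x], key=lambda r: r.well_id)
            ids = [r.well_id for r in group]
            vals = np.array([r.value - background for r in group])
            kept, dropped, kept_vals = _greedy_drop(ids, vals)
            cov = _cov_percent(kept_vals)
            median = float(np.median(kept_vals))
            exempt = cov >= COV_LIMIT and median < LOW_SIGNAL_FRACTION * control_median
            if exempt:
                # heterogeneous death: keep the full group
                kept, dropped, kept_vals = ids, [], np.array(
                    [r.value - background for r in group]
                )
                cov = _cov_percent(kept_vals)
                median = float(np.median(kept_vals))
            passed = cov < COV_LIMIT or exempt
            report.per_concentration.append(
                ConcentrationQC(
                    concentration=float(x),
                    retained_wells=kept,
                    dropped_wells=dropped,
                    median_signal=median,
                    cov_percent=cov,
                    cov_exemption=exempt,
                    passed=passed,
                )
            )
            n_pass += int(passed)
        report.n_passing_concentrations = n_pass
        report.verdict = (
            "accept" if n_pass >= MIN_PASSING_CONCENTRATIONS else "repeat_required"
        )
        reports[chem] = report
    return reports
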