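"""The three comparative analyses over centrality tables.

All three share one statistical recipe: compute a per-residue quantity
(a closeness value or a closeness difference), take its mean and sample
standard deviation across all residues, and flag the residues beyond
mean +/- k standard deviations.

- high_centrality_set: which residues are most connected (k = 1, upper
  side only, inclusive >=).
- delta_centrality: how residue centrality differs between two structures
  — e.g. activated vs inactive conformations (k = 2.5, both sides).
- ligand_effect: how centrality changes when the co-crystallized ligand
  enters the network as one extra node (k = 2.5, upper side only; the
  ligand node counts toward n inside the closeness formula but is
  excluded from the deltas and the threshold statistics).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .centrality import CentralityTable, closeness_centrality
from .contact_detection import ContactCriterion, detect_atomic_contacts, filter_contacts
from .errors import GraphTooSmallError
from .network_build import LIGAND_NODE, build_residue_graph
from .structure_io import Structure

logger = logging.getLogger(__name__)


@dataclass
class ComparisonReport:
    """Per-residue values/deltas, the SD thresholds, and the flags."""

    pairing: tuple[str, str]
    per_residue: dict = field(default_factory=dict)  # key -> (value, flagged)
    mean: float = 0.0
    sd: float = 0.0
    k: float = 1.0
    cutoff_low: float | None = None
    cutoff_high: float | None = None
    unmatched: list = field(default_factory=list)

    def flagged(self) -> list:
        return sorted(k for k, (_, f) in self.per_residue.items() if f)

    def recompute_flags(self) -> dict:
        """Re-derive flags from stored values and thresholds (consistency check)."""
        out = {}
        for key, (v, _) in self.per_residue.items():
            f = False
            if self.cutoff_high is not None and _ge(v, self.cutoff_high):
                f = True
            if self.cutoff_low is not None and _le(v, self.cutoff_low):
                f = True
            out[key] = f
        return out


#: Absolute tolerance for the inclusive threshold comparisons: closeness
#: values and their deltas live in [-1, 1], so 1e-12 is far below any real
#: signal but absorbs the rounding error of mean + k * sd.
_FLAG_ATOL = 1e-12


def _ge(value: float, cutoff: float) -> bool:
    return value >= cutoff - _FLAG_ATOL


def _le(value: float, cutoff: float) -> bool:
    return value <= cutoff + _FLAG_ATOL


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    """Mean and sample (n-1 denominator) standard deviation."""
    m = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return m, sd


def high_centrality_set(t: CentralityTable, k: float = 1.0) -> ComparisonReport:
    """Flag residues with closeness >= mean + k * sd (inclusive).

    The statistic runs over receptor residues only; a ligand node never
    contributes. With sd = 0 (all values equal) the cutoff equals the
    mean and, by the inclusive rule, every residue is flagged.
    """
    vals = t.residue_values(exclude=(LIGAND_NODE,))
    if not vals:
        raise ValueError("centrality table is empty")
    arr = np.array(list(vals.values()))
    mean, sd = _mean_sd(arr)
    cutoff = mean + k * sd
    per = {key: (v, _ge(v, cutoff)) for key, v in vals.items()}
    return ComparisonReport(pairing=(t.structure_id, "none"), per_residue=per,
                            mean=mean, sd=sd, k=k, cutoff_high=cutoff)


def delta_centrality(t_a: CentralityTable, t_b: CentralityTable,
                     k: float = 2.5) -> ComparisonReport:
    """Per-residue delta = C_a - C_b with two-sided mean +/- k*sd flags.

    Residues are matched by key (chain + seq number); unmatched residues
    are listed and excluded from the statistics. With sd = 0 and k > 0
    nothing is flagged (a constant shift carries no per-residue signal).
    """
    va = t_a.residue_values(exclude=(LIGAND_NODE,))
    vb = t_b.residue_values(exclude=(LIGAND_NODE,))
    shared = sorted(set(va) & set(vb))
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared residues between "
                         f"{t_a.structure_id} and {t_b.structure_id} (need >= 2)")
    unmatched = sorted(set(va) ^ set(vb))
    if unmatched:
        logger.warning("%d residues present in only one table", len(unmatched))

    deltas = {key: va[key] - vb[key] for key in shared}
    arr = np.array(list(deltas.values()))
    mean, sd = _mean_sd(arr)
    lo, hi = mean - k * sd, mean + k * sd
    degenerate = sd == 0.0 and k > 0
    per = {key: (d, (not degenerate) and (_ge(d, hi) or _le(d, lo)))
           for key, d in deltas.items()}
    return ComparisonReport(pairing=(t_a.structure_id, t_b.structure_id),
                            per_residue=per, mean=mean, sd=sd, k=k,
                            cutoff_low=lo if not degenerate else None,
                            cutoff_high=hi if not degenerate else None,
                            unmatched=unmatched)


def ligand_effect(s: Structure, crit: ContactCriterion, k: float = 2.5,
                  remove_disulfides: bool = True) -> tuple[ComparisonReport, CentralityTable, CentralityTable]:
    """Centrality change when the ligand joins the network as one node.

    Builds the residue graph twice from the same filtered contacts — with
    and without the ligand node — computes closeness on both, and reports
    delta(r) = C_with(r) - C_without(r) for receptor residues, flagging
    delta >= mean + k * sd (upper side only, inclusive). Returns the
    report plus both tables for downstream output.
    """
    contacts = filter_contacts(detect_atomic_contacts(s, crit), s,
                               remove_disulfides=remove_disulfides)
    g_with = build_residue_graph(contacts, s, include_ligand=True)
    g_without = build_residue_graph(contacts, s, include_ligand=False)
    t_with = closeness_centrality(g_with)
    t_without = closeness_centrality(g_without)

    vw = t_with.residue_values(exclude=(LIGAND_NODE,))
    vo = t_without.residue_values(exclude=(LIGAND_NODE,))
    shared = sorted(set(vw) & set(vo))
    if len(shared) < 2:
        raise GraphTooSmallError("fewer than 2 receptor residues shared between the two runs")
    deltas = {key: vw[key] - vo[key] for key in shared}
    arr = np.array(list(deltas.values()))
    mean, sd = _mean_sd(arr)
    hi = mean + k * sd
    degenerate = sd == 0.0 and k > 0
    per = {key: (d, (not degenerate) and _ge(d, hi)) for key, d in deltas.items()}
    report = ComparisonReport(pairing=(f"{s.structure_id}+ligand", s.structure_id),
                              per_residue=per, mean=mean, sd=sd, k=k,
                              cutoff_high=hi if not degenerate else None)
    return report, t_with, t_without


def pooled_delta_thresholds(reports: list[ComparisonReport], k: float = 2.5) -> tuple[float, float, float]:
    """Mean, sd, and upper cutoff pooled over several reports' deltas."""
    all_vals = np.array([v for r in reports for v, _ in r.per_residue.values()])
    mean, sd = _mean_sd(all_vals)
    return mean, sd, mean + k * sd


def write_report_tsv(report: ComparisonReport, path: str, s: Structure | None = None,
                     scheme=None, header_extra: dict | None = None) -> None:
    """Report TSV with the threshold block in header comments."""
    from .annotation import assign_bw
    by_key = {r.key: r for r in s.residues} if s is not None else {}
    with open(path, "w") as fh:
        fh.write(f"# pairing\t{report.pairing[0]}\t{report.pairing[1]}\n")
        fh.write(f"# mean\t{report.mean:.6f}\n")
        fh.write(f"# sd\t{report.sd:.6f}\t(sample, n-1 denominator)\n")
        fh.write(f"# k\t{report.k:g}\n")
        lo = "" if report.cutoff_low is None else f"{report.cutoff_low:.6f}"
        hi = "" if report.cutoff_high is None else f"{report.cutoff_high:.6f}"
        fh.write(f"# cutoff_low\t{lo}\n# cutoff_high\t{hi}\n")
        for key, val in (header_extra or {}).items():
            fh.write(f"# {key}\t{val}\n")
        fh.write("residue\tres_name\tbw_id\tvalue\tflag\n")
        for key in sorted(report.per_residue):
            chain, seq, icode = key
            v, f = report.per_residue[key]
            r = by_key.get(key)
            name = r.res_name if r is not None else ""
            bw = assign_bw(seq, scheme) if scheme is not None else ""
            fh.write(f"{chain}:{seq}{icode}\t{name}\t{bw}\t{v:.6f}\t{int(f)}\n")


def write_run_summary_json(report: ComparisonReport, path: str, extra: dict | None = None) -> None:
    """Machine-readable run summary: thresholds, flags, provenance."""
    payload = {
        "pairing": list(report.pairing),
        "mean": report.mean,
        "sd": report.sd,
        "sd_kind": "sample (n-1)",
        "k": report.k,
        "cutoff_low": report.cutoff_low,
        "cutoff_high": report.cutoff_high,
        "n_residues": len(report.per_residue),
        "flagged": [f"{c}:{q}{i}" for c, q, i in report.flagged()],
        "unmatched": [f"{c}:{q}{i}" for c, q, i in report.unmatched],
    }
    payload.update(extra or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
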