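"""Heuristic membrane-topology prediction and topology-class assignment.

Transmembrane helices (TMHs) are called from Kyte-Doolittle hydropathy with
TMHMM-era settings: window 19, mean threshold 1.6, merge gap <= 3, helix
span clamped to 15..35 residues.  A signal peptide is a positively charged
n-region followed by a hydrophobic h-region of >= 7 residues within the
first 30 residues, with no further helix starting in residues 31-60.

Topology classes encode the structural signatures used for role inference:
flippases carry 12-14 TMHs (MOP exporter superfamily), DUF2142-containing
polymerases 10-12 TMHs, and co-polymerases a large extracytoplasmic loop
flanked by a signal peptide and a single (or double) C-terminal TMH.

The heuristics deliberately replace deep-learning topology predictors; an
ingestion path for a precomputed per-protein TMH/domain table is provided in
``load_domain_table`` so users can substitute external predictions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "*": 0.0,
}

WINDOW = 19
THRESHOLD = 1.6
MERGE_GAP = 3
MIN_HELIX = 15
MAX_HELIX = 35
_HYDROPHOBIC = set("AILMFVWC")


@dataclass
class TMHProfile:
    helices: list[tuple[int, int]]  # 0-based inclusive residue spans, sorted
    signal_peptide: bool = False
    max_outer_loop: int = 0
    too_short: bool = False  # input shorter than the scan window

    @property
    def count(self) -> int:
        return len(self.helices)


@dataclass
class TopologyClass:
    label: str  # flippase_like | polymerase_like | copolymerase_like | membrane_enzyme | soluble
    evidence: str = ""


def _window_means(seq: str) -> list[float]:
    vals = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq]
    half = WINDOW // 2
    means = [0.0] * len(seq)
    running = sum(vals[:WINDOW])
    for center in range(half, len(seq) - half):
        means[center] = running / WINDOW
        if center + half + 1 < len(seq):
            running += vals[center + half + 1] - vals[center - half]
    return means


def _marked_runs(marked: list[bool]) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, m in enumerate(marked):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(marked) - 1))
    # merge runs separated by small gaps
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= MERGE_GAP:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


def predict_tmh(protein: str) -> TMHProfile:
    """Call TMH spans from windowed mean hydropathy.  Deterministic."""
    seq = protein.upper()
    if len(seq) < WINDOW:
        prof = TMHProfile([], too_short=True)
        prof.max_outer_loop = len(seq)
        return prof
    means = _window_means(seq)
    marked = [m > THRESHOLD for m in means]
    helices: list[tuple[int, int]] = []
    for start, end in _marked_runs(marked):
        width = end - start + 1
        if width < 3:  # spurious single-window spikes
            continue
        if width < MIN_HELIX:
            pad = MIN_HELIX - width
            start = max(0, start - (pad + 1) // 2)
            end = min(len(seq) - 1, start + MIN_HELIX - 1)
            start = max(0, end - MIN_HELIX + 1)
        if end - start + 1 > MAX_HELIX:
            mid = (start + end) // 2
            start = mid - MAX_HELIX // 2
            end = start + MAX_HELIX - 1
        if helices and start <= helices[-1][1]:
            start = helices[-1][1] + 1
            if end - start + 1 < MIN_HELIX:
                continue
        helices.append((start, end))
    # longest non-membrane stretch (termini included: the co-polymerase's
    # large loop lies before its single C-terminal helix)
    loops = []
    prev_end = -1
    for s, e in helices:
        loops.append(s - prev_end - 1)
        prev_end = e
    loops.append(len(seq) - 1 - prev_end)
    prof = TMHProfile(helices=helices, max_outer_loop=max(loops) if loops else len(seq))
    prof.signal_peptide = detect_signal_peptide(seq, prof)
    return prof


def detect_signal_peptide(protein: str, profile: Optional[TMHProfile] = None) -> bool:
    """Sec-type signal peptide heuristic.

    True iff the first 30 residues contain a positively charged n-region
    (K/R within the first 6 residues) followed by a >= 7-residue hydrophobic
    h-region, and no predicted helix starts within residues 31-60.
    """
    seq = protein.upper()
    if len(seq) < 25:
        return False
    head = seq[:30]
    kr = [i for i, c in enumerate(head[:6]) if c in "KR"]
    if not kr:
        return False
    after = head[kr[-1] + 1 :]
    run = best = 0
    for c in after:
        run = run + 1 if c in _HYDROPHOBIC else 0
        best = max(best, run)
    if best < 7:
        return False
    if profile is None:
        if len(seq) < WINDOW:
            return True
        means = _window_means(seq)
        marked = [m > THRESHOLD for m in means]
        runs = [r for r in _marked_runs(marked) if r[1] - r[0] + 1 >= 3]
        helix_starts = [r[0] for r in runs]
    else:
        helix_starts = [s for s, _ in profile.helices]
    return not any(30 <= s < 60 for s in helix_starts)


def classify_topology(profile: TMHProfile, domain_hints: Iterable[str] = ()) -> TopologyClass:
    """Deterministic topology-class assignment.

    Precedence is fixed: a DUF2142 hint with 10-12 TMHs is polymerase_like
    even at count 12 where the flippase band (12-14) also matches.
    """
    hints = {h.upper() for h in domain_hints}
    duf2142 = any("DUF2142" in h for h in hints)
    n = profile.count
    if duf2142 and 10 <= n <= 12:
        return TopologyClass("polymerase_like", f"DUF2142 + {n} TMHs")
    if 12 <= n <= 14 and not duf2142:
        return TopologyClass("flippase_like", f"{n} TMHs, MOP-exporter-like")
    if profile.signal_peptide and n <= 2 and profile.max_outer_loop >= 100:
        return TopologyClass(
            "copolymerase_like",
            f"signal peptide + {profile.max_outer_loop}-residue loop + {n} TMH(s)",
        )
    if n >= 1:
        return TopologyClass("membrane_enzyme", f"{n} TMHs")
    return TopologyClass("soluble", "no TMHs")


@dataclass
class DomainRecord:
    protein_id: str
    n_tmh: Optional[int] = None
    signal_peptide: Optional[bool] = None
    domains: set[str] = field(default_factory=set)


def load_domain_table(path: str | Path) -> dict[str, DomainRecord]:
    """Ingest a precomputed domain/topology TSV.

    Columns: protein_id, n_tmh, signal_peptide, domains (semicolon-separated).
    Values override the heuristics where present.
    """
    out: dict[str, DomainRecord] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rec = DomainRecord(protein_id=row["protein_id"])
            if row.get("n_tmh"):
                rec.n_tmh = int(row["n_tmh"])
            if row.get("signal_peptide"):
                rec.signal_peptide = row["signal_peptide"].strip().lower() in ("1", "true", "yes")
            if row.get("domains"):
                rec.domains = {d.strip() for d in row["domains"].split(";") if d.strip()}
            out[rec.protein_id] = rec
    return out
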