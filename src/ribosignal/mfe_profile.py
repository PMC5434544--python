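"""Sliding-window folding-score profiles around start and stop codons.

Local mRNA secondary structure that buries the ribosome-binding region or
the start codon slows translation initiation; a hairpin just downstream of
the stop codon is the signature of rho-independent termination.  Both show
up as features in per-position folding-score profiles: fold a sliding
window over a region anchored at the start (or stop) codon, assign each
window's score to its 5'-most position, and average across genes.

Region conventions (flank = cds_span = 100 by default):

* start anchor — last 100 nt of the upstream flank + first 100 nt of CDS,
  so the start codon occupies sites 101-103;
* stop anchor — last 100 nt of CDS + first 100 nt downstream, so the stop
  codon occupies sites 98-100.

The built-in engine is a weighted base-pair-maximization dynamic program
over nested structures (pair scores GC=-3, AU=-2, GU=-1, minimum hairpin
loop 3): self-contained, exactly verifiable against brute-force structure
enumeration, and adequate for profile shapes.  Scores are in arbitrary
negative units; a thermodynamic folder (e.g. ViennaRNA) can be plugged in
through the same engine contract for kcal/mol energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FoldScore",
    "PositionProfile",
    "NussinovEngine",
    "ViennaRNAEngine",
    "fold_window",
    "extract_regions",
    "sliding_profile",
    "aggregate_profiles",
    "profile_anchor",
    "heg_leg_by_ite",
]

_IUPAC = set("ACGUTNRYSWKMBDHV")
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

#: default pair scores, symmetric; 0 = cannot pair
DEFAULT_PAIR_SCORES = {("G", "C"): -3.0, ("A", "U"): -2.0, ("G", "U"): -1.0}


@dataclass(frozen=True)
class FoldScore:
    """Optimal folding score (<= 0) and one optimal dot-bracket structure."""

    score: float
    structure: str
    engine: str = ""


def _weight_matrix(pair_scores: Mapping[tuple[str, str], float]) -> np.ndarray:
    W = np.zeros((5, 5))
    for (x, y), v in pair_scores.items():
        i, j = _CODE[x.upper()], _CODE[y.upper()]
        W[i, j] = v
        W[j, i] = v
    return W


def _encode(seq: str) -> np.ndarray:
    s = seq.upper()
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return np.array([_CODE.get(b, 4) for b in s], dtype=np.int64)


def _fill_python(codes: np.ndarray, W: np.ndarray, min_loop: int) -> np.ndarray:
    n = len(codes)
    E = np.zeros((n + 1, max(n, 1)))
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = W[codes[i], codes[k]]
                if w < 0.0:
                    v = w + E[i + 1, k - 1] + E[k + 1, j]
                    if v < best:
                        best = v
            E[i, j] = best
    return E

_fill = None  # jitted lazily on first fold


def _get_fill() -> Callable:
    global _fill
    if _fill is None:
        try:
            from numba import njit

            _fill = njit(cache=True)(_fill_python)
        except ImportError:  # pragma: no cover - numba is a declared dependency
            _fill = _fill_python
    return _fill


class NussinovEngine:
    """Weighted base-pair maximization over nested structures.

    Recurrence on the optimal score E(i,j) of subsequence i..j:
    either i is unpaired (E(i+1,j)) or i pairs with some k>i+min_loop
    (w(i,k) + E(i+1,k-1) + E(k+1,j)); ambiguity codes never pair.
    Traceback prefers pairing the 5'-most base with its 5'-most optimal
    partner, so structures are deterministic; the score is unaffected.
    """

    def __init__(
        self,
        pair_scores: Optional[Mapping[tuple[str, str], float]] = None,
        min_loop: int = 3,
    ):
        if min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        self.pair_scores = dict(pair_scores or DEFAULT_PAIR_SCORES)
        if any(v >= 0 for v in self.pair_scores.values()):
            raise ValueError("pair scores must be negative")
        self.min_loop = min_loop
        self._W = _weight_matrix(self.pair_scores)
        self.name = "builtin-pairmax"

    def score(self, seq: str) -> float:
        codes = _encode(seq)
        if len(codes) < 2:
            return 0.0
        E = _get_fill()(codes, self._W, self.min_loop)
        return float(E[0, len(codes) - 1])

    def fold(self, seq: str) -> FoldScore:
        codes = _encode(seq)
        n = len(codes)
        if n == 0:
            raise ValueError("empty sequence")
        if n < 2:
            return FoldScore(0.0, "." * n, self.name)
        E = _get_fill()(codes, self._W, self.min_loop)
        struct = ["."] * n
        stack = [(0, n - 1)]
        eps = 1e-9
        while stack:
            i, j = stack.pop()
            if j - i <= self.min_loop:
                continue
            target = E[i, j]
            if target >= -eps:
                continue
            paired = False
            for k in range(i + self.min_loop + 1, j + 1):
                w = self._W[codes[i], codes[k]]
                if w < 0.0:
                    left = E[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                    right = E[k + 1, j] if k + 1 <= j else 0.0
                    if abs(w + left + right - target) <= eps:
                        struct[i], struct[k] = "(", ")"
                        stack.append((i + 1, k - 1))
                        stack.append((k + 1, j))
                        paired = True
                        break
            if not paired:
                stack.append((i + 1, j))
        return FoldScore(float(E[0, n - 1]), "".join(struct), self.name)


class ViennaRNAEngine:
    """Thermodynamic MFE folding via the ViennaRNA python bindings.

    Optional plug-in honouring the same contract as the built-in engine;
    scores are free energies in kcal/mol.
    """

    def __init__(self) -> None:
        import RNA  # deferred; only needed when this engine is chosen

        self._RNA = RNA
        self.name = "viennarna"

    def fold(self, seq: str) -> FoldScore:
        _encode(seq)  # same input validation as the built-in engine
        structure, mfe = self._RNA.fold(seq.upper().replace("T", "U"))
        return FoldScore(float(mfe), structure, self.name)

    def score(self, seq: str) -> float:
        return self.fold(seq).score


def fold_window(seq: str, engine=None, min_loop: int = 3) -> FoldScore:
    """Fold one window; ``engine`` defaults to the built-in pair-maximizer."""
    if engine is None:
        engine = NussinovEngine(min_loop=min_loop)
    return engine.fold(seq)


def extract_regions(
    records: Iterable,
    anchor: str,
    flank: int = 100,
    cds_span: int = 100,
) -> list[tuple[str, str]]:
    """Anchor-centred regions for profiling, one per gene.

    Genes whose CDS (or flank) is too short for the requested span are
    dropped with a logged count.  Callers normally pre-filter with
    :func:`ribosignal.genome_io.filter_by_intergenic_distance` so closely
    spaced neighbours do not confound the profile.
    """
    if anchor not in {"start", "stop"}:
        raise ValueError("anchor must be 'start' or 'stop'")
    out: list[tuple[str, str]] = []
    dropped = 0
    for r in records:
        if anchor == "start":
            if len(r.upstream_seq) < flank or len(r.cds_seq) < cds_span:
                dropped += 1
                continue
            region = r.upstream_seq[-flank:] + r.cds_seq[:cds_span]
        else:
            if len(r.cds_seq) < cds_span or len(r.downstream_seq) < flank:
                dropped += 1
                continue
            region = r.cds_seq[-cds_span:] + r.downstream_seq[:flank]
        out.append((r.locus_tag, region))
    if dropped:
        logger.info("extract_regions(%s): dropped %d short genes", anchor, dropped)
    if not out:
        raise ValueError("no gene long enough for the requested region")
    return out


def sliding_profile(
    region: str, engine=None, window: int = 40, step: int = 1
) -> np.ndarray:
    """Fold every window of the region; score i belongs to the window whose
    5' end is at site i+1 (1-based)."""
    if engine is None:
        engine = NussinovEngine()
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if len(region) < window:
        raise ValueError(f"region length {len(region)} < window {window}")
    scorer = getattr(engine, "score", None) or (lambda s: engine.fold(s).score)
    n_win = (len(region) - window) // step + 1
    return np.array([scorer(region[i * step : i * step + window]) for i in range(n_win)])


@dataclass
class PositionProfile:
    """Per-position mean/sd/n of window scores for one gene class."""

    anchor: str
    label: str
    mean: np.ndarray
    sd: np.ndarray
    n: int
    window: int
    step: int

    @property
    def positions(self) -> np.ndarray:
        """1-based site of each window's 5' end."""
        return np.arange(len(self.mean)) * self.step + 1


def aggregate_profiles(
    score_tracks: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
    labels: Optional[Mapping[str, str]] = None,
    anchor: str = "start",
    window: int = 40,
    step: int = 1,
) -> dict[str, PositionProfile]:
    """Average score tracks per gene class.

    ``labels`` maps locus_tag to a class name (e.g. HEG/LEG); unlabeled
    genes raise.  With ``labels=None`` all genes form one class ``"all"``.
    """
    items = list(score_tracks.items()) if isinstance(score_tracks, Mapping) else list(score_tracks)
    if not items:
        raise ValueError("no score tracks")
    length = len(items[0][1])
    by_class: dict[str, list[np.ndarray]] = {}
    for locus, track in items:
        if len(track) != length:
            raise ValueError("score tracks have unequal lengths")
        label = "all" if labels is None else labels.get(locus)
        if label is None:
            raise ValueError(f"no class label for gene {locus!r}")
        by_class.setdefault(label, []).append(np.asarray(track, dtype=float))
    out = {}
    for label, tracks in by_class.items():
        arr = np.vstack(tracks)
        out[label] = PositionProfile(
            anchor=anchor,
            label=label,
            mean=arr.mean(axis=0),
            sd=arr.std(axis=0, ddof=1) if len(tracks) > 1 else np.zeros(length),
            n=len(tracks),
            window=window,
            step=step,
        )
    return out


def profile_anchor(
    records: Iterable,
    anchor: str,
    engine=None,
    labels: Optional[Mapping[str, str]] = None,
    window: int = 40,
    step: int = 1,
    flank: int = 100,
    cds_span: int = 100,
) -> dict[str, PositionProfile]:
    """extract_regions + sliding_profile + aggregate_profiles in one call."""
    if engine is None:
        engine = NussinovEngine()
    regions = extract_regions(records, anchor, flank=flank, cds_span=cds_span)
    tracks = [(locus, sliding_profile(seq, engine, window=window, step=step)) for locus, seq in regions]
    return aggregate_profiles(tracks, labels, anchor=anchor, window=window, step=step)


def heg_leg_by_ite(records: Sequence, wtable, n_top: int = 1000) -> dict[str, str]:
    """Label the top/bottom ``n_top`` genes by I_TE as HEG/LEG.

    Fallback classification when no expression ranking is supplied; genes in
    the middle of the ranking receive no label.
    """
    from .ite import ite_score

    scored = []
    for r in records:
        try:
            scored.append((ite_score(r.cds_seq, wtable).score, r.locus_tag))
        except ValueError:
            continue
    scored.sort(reverse=True)
    labels: dict[str, str] = {}
    for _, locus in scored[:n_top]:
        labels[locus] = "HEG"
    for _, locus in scored[-n_top:]:
        labels.setdefault(locus, "LEG")
    return labels
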