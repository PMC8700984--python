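"""Homology annotation, reciprocal cross-species search and core-set extraction.

Desk-scale stand-in for BLAST-based comparison of shell matrix protein (SMP)
sets: Smith-Waterman local alignment with BLOSUM62 and affine gaps supplies
raw scores, a Karlin-Altschul formula turns scores into e-values, and two
stringency settings gate the hits — Setting 1 (e-value < 1e-5 AND identity
>= 50%) and Setting 2 (e-value < 1e-5 alone). Reciprocal hits across five
species populate a boolean presence matrix whose rows are then partitioned
into all-conchiferan, marine-only, pair-shared and focal-specific core sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    raw_score: float
    percent_identity: float  # over aligned columns, gap columns included
    evalue: float
    aligned_query_span: tuple[int, int]  # 0-based half-open
    aligned_subject_span: tuple[int, int]


@dataclass(frozen=True)
class SearchSetting:
    name: str
    max_evalue: float = 1e-5
    min_identity: Optional[float] = None  # percent; None disables the filter

    def passes(self, hit: AlignmentHit) -> bool:
        if hit.evalue >= self.max_evalue:
            return False
        if self.min_identity is not None and hit.percent_identity < self.min_identity:
            return False
        return True


#: e-value < 1e-5 and identity >= 50% (the stringent setting).
SETTING1 = SearchSetting("setting1", 1e-5, 50.0)
#: e-value < 1e-5 alone (the relaxed setting).
SETTING2 = SearchSetting("setting2", 1e-5, None)


@lru_cache(maxsize=4)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment with affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend``. Identity is the
    fraction of matching residues over all aligned columns, gap columns
    included. If no cell scores positive the hit has raw_score 0, identity 0
    and empty spans.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    aligner = _aligner(matrix_name, gap_open, gap_extend)
    score = aligner.score(query, subject)
    if score <= 0:
        return AlignmentHit(query_id, subject_id, 0.0, 0.0, math.inf, (0, 0), (0, 0))
    aln = aligner.align(query, subject)[0]
    q_blocks, s_blocks = aln.aligned
    matches = 0
    columns = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        if prev_q is not None:
            columns += (qs - prev_q) + (ss - prev_s)  # internal gap columns
        for i in range(qe - qs):
            columns += 1
            if query[qs + i] == subject[ss + i]:
                matches += 1
        prev_q, prev_s = qe, se
    identity = 100.0 * matches / columns if columns else 0.0
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    return AlignmentHit(query_id, subject_id, float(score), identity, math.nan, q_span, s_span)


def estimate_evalue(
    raw_score: float,
    query_len: int,
    subject_db_len: int,
    lam: float = 0.267,
    K: float = 0.041,
) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S).

    The constants are fixed gapped-BLOSUM62 defaults used as a declared
    calibration, not fitted to any search space.
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return K * query_len * subject_db_len * math.exp(-lam * raw_score)


def _with_evalue(hit: AlignmentHit, query_len: int, db_len: int) -> AlignmentHit:
    if hit.raw_score <= 0:
        return hit
    ev = estimate_evalue(hit.raw_score, query_len, db_len)
    return AlignmentHit(
        hit.query_id, hit.subject_id, hit.raw_score, hit.percent_identity,
        ev, hit.aligned_query_span, hit.aligned_subject_span,
    )


def _best_hit(hits: Iterable[AlignmentHit]) -> Optional[AlignmentHit]:
    best = None
    for h in hits:
        if best is None or (-h.raw_score, h.subject_id) < (-best.raw_score, best.subject_id):
            best = h
    return best


def annotate(
    queries: Mapping[str, str],
    reference_db: Mapping[str, str],
    setting: SearchSetting = SETTING2,
    fpkm: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Best reference hit per query under a search setting, else "None".

    Output schema mirrors the study's annotation table: query id, FPKM (when
    supplied), best-hit label, e-value, percent identity.
    """
    if not reference_db:
        raise ValueError("reference database is empty")
    db_len = sum(len(s) for s in reference_db.values())
    rows = []
    for qid, qseq in queries.items():
        hits = [
            _with_evalue(local_align(qseq, sseq, query_id=qid, subject_id=sid),
                         len(qseq), db_len)
            for sid, sseq in reference_db.items()
        ]
        best = _best_hit([h for h in hits if setting.passes(h)])
        rows.append({
            "id": qid,
            "fpkm": fpkm.get(qid) if fpkm else None,
            "annotation": best.subject_id if best else "None",
            "evalue": best.evalue if best else None,
            "percent_identity": best.percent_identity if best else None,
        })
    return pd.DataFrame(rows)


class PresenceMatrix:
    """Boolean species x feature matrix (features as rows)."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] and data.shape[1] and data.dtypes.nunique() > 1:
            raise ValueError("presence matrix must be homogeneous boolean")
        self.data = data.astype(bool)

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def cell(self, feature: str, species: str) -> bool:
        return bool(self.data.loc[feature, species])

    def n_true(self) -> int:
        return int(self.data.values.sum())

    @classmethod
    def from_dict(cls, presence: Mapping[str, Iterable[str]], species: list[str]) -> "PresenceMatrix":
        """Build from {feature: [species where present]}."""
        df = pd.DataFrame(
            {sp: [sp in set(present) for present in presence.values()] for sp in species},
            index=list(presence.keys()),
        )
        return cls(df)

    def to_tsv(self, path) -> None:
        self.data.astype(int).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0).astype(bool))


def reciprocal_search(
    focal_set: Mapping[str, str],
    other_sets: Mapping[str, Mapping[str, str]],
    setting: SearchSetting = SETTING2,
    focal_name: str = "Nautilus",
    reciprocal: bool = True,
    strict_rbh: bool = False,
) -> PresenceMatrix:
    """Presence matrix of focal proteins across species via reciprocal search.

    cell(p, s) is true iff p has a hit in species s passing the setting and
    (default mode) that subject's best hit back into the focal set also passes
    the setting. With ``strict_rbh`` the subject's best hit back must be p
    itself and p's best forward hit must be that subject. The focal column is
    always true. Equal scores are broken toward the lexicographically smallest
    subject id.
    """
    if len(other_sets) < 1:
        raise ValueError("need at least one non-focal species")
    for sp, prots in other_sets.items():
        if not prots:
            raise ValueError(f"species {sp} has an empty protein set")
    focal_len = sum(len(s) for s in focal_set.values())
    species = [focal_name] + sorted(other_sets)
    cells = {pid: {focal_name: True} for pid in focal_set}
    for sp in sorted(other_sets):
        subjects = other_sets[sp]
        db_len = sum(len(s) for s in subjects.values())
        # score every focal x subject pair once; alignment score is symmetric
        pair_hits: dict[tuple[str, str], AlignmentHit] = {}
        for pid, pseq in focal_set.items():
            for sid, sseq in subjects.items():
                pair_hits[(pid, sid)] = local_align(
                    pseq, sseq, query_id=pid, subject_id=sid
                )
        # best hit of each subject back into the focal set
        back_best: dict[str, Optional[AlignmentHit]] = {}
        for sid, sseq in subjects.items():
            back = [
                _with_evalue(
                    AlignmentHit(sid, pid, h.raw_score, h.percent_identity,
                                 math.nan, h.aligned_subject_span, h.aligned_query_span),
                    len(sseq), focal_len,
                )
                for (pid, s2), h in pair_hits.items() if s2 == sid
            ]
            back_best[sid] = _best_hit([b for b in back if setting.passes(b)])
        for pid, pseq in focal_set.items():
            fwd = [
                _with_evalue(pair_hits[(pid, sid)], len(pseq), db_len)
                for sid in subjects
            ]
            fwd_pass = [h for h in fwd if setting.passes(h)]
            present = False
            if strict_rbh:
                best_fwd = _best_hit(fwd_pass)
                if best_fwd is not None:
                    bb = back_best[best_fwd.subject_id]
                    present = bb is not None and bb.subject_id == pid
            else:
                for h in fwd_pass:
                    if not reciprocal or back_best[h.subject_id] is not None:
                        present = True
                        break
            cells[pid][sp] = present
    df = pd.DataFrame(
        {sp: [cells[pid].get(sp, False) for pid in focal_set] for sp in species},
        index=list(focal_set),
    )
    return PresenceMatrix(df)


@dataclass
class CoreSets:
    shared_all: list[str]
    shared_marine_only: list[str]
    focal_specific: list[str]
    pair_shared: dict[str, list[str]]  # partner species -> features
    other: list[str]

    @property
    def shared_marine(self) -> list[str]:
        """Features conserved across all marine species (includes shared_all)."""
        return self.shared_all + self.shared_marine_only

    def classify(self) -> dict[str, str]:
        labels = {}
        for f in self.shared_all:
            labels[f] = "shared_all"
        for f in self.shared_marine_only:
            labels[f] = "marine_only"
        for f in self.focal_specific:
            labels[f] = "focal_specific"
        for sp, feats in self.pair_shared.items():
            for f in feats:
                labels[f] = f"pair_shared:{sp}"
        for f in self.other:
            labels[f] = "other"
        return labels


def core_sets(
    matrix: PresenceMatrix,
    focal: str,
    group_all: Iterable[str],
    group_marine: Iterable[str],
) -> CoreSets:
    """Partition matrix rows into conservation classes.

    shared_all: present in every species of ``group_all``; shared_marine_only:
    present in every marine species but not shared_all; focal_specific:
    present only in the focal species; pair_shared: present in the focal
    species plus exactly one other. Remaining patterns go to ``other``.
    """
    group_all = list(group_all)
    group_marine = list(group_marine)
    for sp in group_all + group_marine + [focal]:
        if sp not in matrix.species:
            raise ValueError(f"species {sp} not in matrix")
    shared_all, marine_only, focal_specific, other = [], [], [], []
    pair_shared: dict[str, list[str]] = {}
    for feat in matrix.features:
        present = {sp for sp in matrix.species if matrix.cell(feat, sp)}
        if set(group_all) <= present:
            shared_all.append(feat)
        elif set(group_marine) <= present:
            marine_only.append(feat)
        elif present == {focal}:
            focal_specific.append(feat)
        elif focal in present and len(present) == 2:
            partner = next(iter(present - {focal}))
            pair_shared.setdefault(partner, []).append(feat)
        else:
            other.append(feat)
    return CoreSets(shared_all, marine_only, focal_specific, pair_shared, other)
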