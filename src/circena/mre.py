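"""miRNA response element (MRE) prediction by seed matching + duplex scoring.

A target site is an exact Watson-Crick match (no G:U in the seed) of
the miRNA seed (nucleotides 2-7, the 6mer core) on the target,
classified upward by the canonical site hierarchy: pairing at position
8 gives 7mer-m8, an A opposite position 1 gives 7mer-A1, both give
8mer.  Site strength is a transparent local-alignment duplex score of
the full miRNA against the site's 3'-extended window: Watson-Crick +5,
G:U wobble +1, mismatch -3, gap open -8, gap extend -2, with the seed
region weighted x2.  The constants are deliberately simple and
recorded in output metadata; the scorer is a strength heuristic, not a
free-energy model (a dG hook can be plugged in via ``scorer``).

circRNA targets are scanned on the circularized sequence (the first 30
nt appended) so junction-spanning sites are found; duplicates at the
wrap are removed by modular position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MiRNA",
    "MRESite",
    "seed_match_sites",
    "duplex_score",
    "predict_targets",
    "SEED_CLASSES",
    "DUPLEX_PARAMS",
    "CIRC_WRAP_NT",
]

SEED_CLASSES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
_CLASS_RANK = {c: i for i, c in enumerate(SEED_CLASSES)}
# minimum rank implied by a min_seed_class setting; "7mer" admits both 7mers
_MIN_CLASS_RANK = {"6mer": 0, "7mer": 1, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

DUPLEX_PARAMS = {
    "match": 5.0,
    "gu_wobble": 1.0,
    "mismatch": -3.0,
    "gap_open": -8.0,
    "gap_extend": -2.0,
    "seed_weight": 2.0,
    "window_extension": 10,
}

CIRC_WRAP_NT = 30

_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, 5'->3'; the seed is nucleotides 2-8."""

    mirna_id: str
    sequence: str  # RNA alphabet, U allowed (normalized from T on input)

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 15:
            raise ValueError(f"miRNA {self.mirna_id!r} shorter than 15 nt")
        bad = set(seq) - set("ACGU")
        if bad:
            raise ValueError(f"miRNA {self.mirna_id!r} has non-RNA characters {bad}")

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 (7 nt)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class MRESite:
    """A predicted miRNA binding site on a target sequence.

    ``start``/``end`` are 1-based inclusive on the target; the matched
    subsequence is the reverse complement of the miRNA positions the
    seed class implies (with the A1 adenine, when present, at the 3'
    end of the interval).
    """

    target_id: str
    mirna_id: str
    start: int
    end: int
    seed_class: str
    duplex_score: float = np.nan

    def __post_init__(self) -> None:
        if self.seed_class not in SEED_CLASSES:
            raise ValueError(f"unknown seed class {self.seed_class!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid site interval")


def _pair_type(mi_base: str, tg_base: str) -> str:
    """'wc', 'gu', or 'mm' for a miRNA(RNA) vs target(DNA) base pair."""
    mi_dna = "T" if mi_base == "U" else mi_base
    if _DNA_COMPLEMENT.get(mi_dna) == tg_base:
        return "wc"
    if (mi_base, tg_base) in (("G", "T"), ("U", "G")):
        return "gu"
    return "mm"


def seed_match_sites(
    mirna: MiRNA, target_id: str, target_sequence: str, circular: bool = False
) -> list[MRESite]:
    """All seed-matched sites of one miRNA on one target, sorted by position.

    Scans every offset for an exact Watson-Crick match of the 6mer core
    (miRNA 2-7) and classifies upward: position-8 pairing promotes to
    7mer-m8, an A opposite position 1 to 7mer-A1, both to 8mer.  With
    ``circular`` the first ``CIRC_WRAP_NT`` nt are appended so sites
    spanning the back-splice junction are found; wrap duplicates are
    removed by modular position.
    """
    target = _to_dna(target_sequence)
    length = len(target)
    scan = target + target[:CIRC_WRAP_NT] if circular else target
    mi = mirna.sequence
    core = mi[1:7]
    sites: list[MRESite] = []
    seen_mod: set[int] = set()
    # positions pair antiparallel: target position i+k pairs miRNA position
    # (core end - k); the core occupies target [i, i+5] pairing miRNA 7..2.
    for i in range(len(scan) - 6 + 1):
        window = scan[i : i + 6]
        if any(_pair_type(core[5 - k], window[k]) != "wc" for k in range(6)):
            continue
        # check position 8 (pairs the base just before the core on the target)
        m8 = (
            i - 1 >= 0
            and len(mi) >= 8
            and _pair_type(mi[7], scan[i - 1]) == "wc"
        )
        # check the A opposite position 1 (just after the core on the target)
        a1 = i + 6 < len(scan) and scan[i + 6] == "A"
        if m8 and a1:
            seed_class, start0, end0 = "8mer", i - 1, i + 6
        elif m8:
            seed_class, start0, end0 = "7mer-m8", i - 1, i + 5
        elif a1:
            seed_class, start0, end0 = "7mer-A1", i, i + 6
        else:
            seed_class, start0, end0 = "6mer", i, i + 5
        start_mod = start0 % length if circular else start0
        if circular:
            if start0 >= length:
                continue  # whole site inside the appended wrap: duplicate
            if start_mod in seen_mod:
                continue
        seen_mod.add(start_mod)
        sites.append(
            MRESite(
                target_id=target_id,
                mirna_id=mirna.mirna_id,
                start=start0 + 1,
                end=end0 + 1,
                seed_class=seed_class,
            )
        )
    sites.sort(key=lambda s: (s.start, s.end))
    return sites


def duplex_score(
    mirna: MiRNA,
    target_sequence: str,
    site: MRESite,
    params: Mapping[str, float] | None = None,
    circular: bool = False,
) -> float:
    """Local-alignment duplex score of the miRNA against the site window.

    The window is the site extended 3'-ward on the miRNA (= upstream on
    the target) to miRNA length + 10 nt.  Alignment is affine-gap local
    (Smith-Waterman) between the miRNA 5'->3' and the reversed window,
    pairing scored Watson-Crick +5 / G:U +1 / mismatch -3, gaps -8/-2,
    and positions 2-8 of the miRNA weighted x2.  A perfect full-length
    complement of a length-L miRNA scores 2*5*7 + 5*(L-7).
    """
    p = dict(DUPLEX_PARAMS)
    if params:
        p.update(params)
    target = _to_dna(target_sequence)
    if circular:
        target = target + target[: CIRC_WRAP_NT]
    window_len = len(mirna.sequence) + int(p["window_extension"])
    end0 = site.end  # 1-based inclusive -> exclusive 0-based == site.end
    start0 = max(0, end0 - window_len)
    window = target[start0:end0]
    # antiparallel: miRNA 5'->3' pairs the window read 3'->5'
    return _local_duplex(mirna.sequence, window[::-1], p)


def _local_duplex(mi: str, tg_rev: str, p: Mapping[str, float]) -> float:
    """Affine-gap Smith-Waterman with position-weighted pair scores."""
    n, m = len(mi), len(tg_rev)
    neg = -np.inf
    M = np.zeros((n + 1, m + 1))          # pair state
    X = np.full((n + 1, m + 1), neg)      # gap in target (miRNA base unpaired)
    Y = np.full((n + 1, m + 1), neg)      # gap in miRNA
    best = 0.0
    for i in range(1, n + 1):
        weight = p["seed_weight"] if 1 <= i - 1 <= 7 else 1.0
        for j in range(1, m + 1):
            kind = _pair_type(mi[i - 1], tg_rev[j - 1])
            s = {"wc": p["match"], "gu": p["gu_wobble"], "mm": p["mismatch"]}[kind]
            s *= weight
            prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1], 0.0)
            M[i, j] = prev + s
            X[i, j] = max(M[i - 1, j] + p["gap_open"], X[i - 1, j] + p["gap_extend"])
            Y[i, j] = max(M[i, j - 1] + p["gap_open"], Y[i, j - 1] + p["gap_extend"])
            best = max(best, M[i, j])
    return float(best)


def predict_targets(
    mirnas: Iterable[MiRNA],
    targets: Mapping[str, str],
    min_seed_class: str = "7mer",
    min_duplex_score: float = 80.0,
    circular_targets: set[str] | None = None,
    params: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction table over all (miRNA, target) pairs.

    A site qualifies when its seed class reaches ``min_seed_class``
    ("7mer" admits both 7mer-A1 and 7mer-m8) and its duplex score
    reaches ``min_duplex_score``.  Returns (sites, interactions):
    per-site rows, and per-pair rows with site count and best score for
    pairs with at least one qualifying site.
    """
    if min_seed_class not in _MIN_CLASS_RANK:
        raise ValueError(f"unknown min_seed_class {min_seed_class!r}")
    min_rank = _MIN_CLASS_RANK[min_seed_class]
    circular_targets = circular_targets or set()
    site_rows = []
    pair_rows = []
    for mirna in mirnas:
        for target_id, seq in targets.items():
            circ = target_id in circular_targets
            qualifying = []
            for site in seed_match_sites(mirna, target_id, seq, circular=circ):
                if _CLASS_RANK[site.seed_class] < min_rank:
                    continue
                score = duplex_score(mirna, seq, site, params=params, circular=circ)
                if score < min_duplex_score:
                    continue
                qualifying.append((site, score))
                site_rows.append(
                    (target_id, mirna.mirna_id, site.start, site.end,
                     site.seed_class, score)
                )
            if qualifying:
                pair_rows.append(
                    (
                        mirna.mirna_id,
                        target_id,
                        len(qualifying),
                        max(score for _, score in qualifying),
                    )
                )
    sites = pd.DataFrame(
        site_rows,
        columns=["target_id", "mirna_id", "start", "end", "seed_class", "duplex_score"],
    )
    interactions = pd.DataFrame(
        pair_rows, columns=["mirna_id", "target_id", "n_sites", "best_score"]
    )
    return sites, interactions
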