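"""ceRNA triad assembly: circRNA - miRNA - mRNA units.

A triad is kept when (i) a miRNA has at least one qualifying binding
site on both the circRNA and the mRNA (the shared-MRE rule), (ii) the
circRNA and mRNA are significantly and positively co-expressed, and
(iii) both are differentially expressed in the same direction — the
sponge model: the circle and the target co-vary because the circle
sequesters the miRNA that represses the target.  When miRNA expression
is available, a fourth gate requires the miRNA to move opposite to the
pair; it is optional because miRNA levels are often measured only by
qPCR, outside the RNA-seq.  Triads are ranked by |r| x min(site
counts), a transparent heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["CeRNATriad", "shared_mirnas", "assemble_triads", "triad_report"]


@dataclass
class CeRNATriad:
    """One circRNA - miRNA - mRNA unit with its supporting evidence."""

    circ_id: str
    mirna_id: str
    mrna_id: str
    n_circ_sites: int
    n_mrna_sites: int
    circ_mrna_r: float
    circ_direction: str
    mrna_direction: str
    mirna_direction: str | None = None
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_circ_sites < 1 or self.n_mrna_sites < 1:
            raise ValueError("a triad requires sites on both the circRNA and mRNA")
        self.score = abs(self.circ_mrna_r) * min(self.n_circ_sites, self.n_mrna_sites)


def shared_mirnas(
    circ_interactions: pd.DataFrame, mrna_interactions: pd.DataFrame
) -> dict[tuple[str, str], set[str]]:
    """miRNAs with qualifying sites on both members of each circ-mRNA pair.

    Inputs are interaction tables (mirna_id, target_id, n_sites, ...)
    from MRE prediction, one for circRNA targets and one for mRNAs.
    """
    out: dict[tuple[str, str], set[str]] = {}
    if circ_interactions.empty or mrna_interactions.empty:
        return out
    circ_by_mir = circ_interactions.groupby("mirna_id")["target_id"].agg(set)
    mrna_by_mir = mrna_interactions.groupby("mirna_id")["target_id"].agg(set)
    for mirna_id in set(circ_by_mir.index) & set(mrna_by_mir.index):
        for circ_id in circ_by_mir[mirna_id]:
            for mrna_id in mrna_by_mir[mirna_id]:
                out.setdefault((circ_id, mrna_id), set()).add(mirna_id)
    return out


def assemble_triads(
    shared: Mapping[tuple[str, str], set[str]],
    circ_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    correlations: pd.DataFrame,
    circ_interactions: pd.DataFrame,
    mrna_interactions: pd.DataFrame,
    mirna_de: pd.DataFrame | None = None,
    direction_gate: bool = True,
) -> list[CeRNATriad]:
    """Triads passing the shared-site, correlation and concordance gates.

    ``circ_de`` / ``mrna_de`` are DE tables with feature_id, called and
    direction columns; ``correlations`` has circ_id, mrna_id, r, p rows
    for significantly correlated pairs (only positive r qualifies: a
    sponge and its target co-vary).  ``mirna_de``, when given, adds the
    anti-correlation gate on the miRNA; ``direction_gate=False``
    disables the concordance requirements (gates iii-iv).
    Result is sorted by score descending, ties by ids.
    """
    circ_called = _called_directions(circ_de)
    mrna_called = _called_directions(mrna_de)
    mirna_called = _called_directions(mirna_de) if mirna_de is not None else None
    corr = {
        (row.circ_id, row.mrna_id): float(row.r)
        for row in correlations.itertuples()
    }
    circ_sites = _site_counts(circ_interactions)
    mrna_sites = _site_counts(mrna_interactions)

    triads: list[CeRNATriad] = []
    for (circ_id, mrna_id), mirnas in shared.items():
        if circ_id not in circ_called or mrna_id not in mrna_called:
            continue
        r = corr.get((circ_id, mrna_id))
        if r is None or r <= 0:
            continue
        circ_dir = circ_called[circ_id]
        mrna_dir = mrna_called[mrna_id]
        if direction_gate and circ_dir != mrna_dir:
            continue
        for mirna_id in sorted(mirnas):
            mirna_dir: str | None = None
            if mirna_called is not None:
                mirna_dir = mirna_called.get(mirna_id)
                if direction_gate:
                    if mirna_dir is None:
                        continue
                    opposite = {"up": "down", "down": "up"}[circ_dir]
                    if mirna_dir != opposite:
                        continue
            triads.append(
                CeRNATriad(
                    circ_id=circ_id,
                    mirna_id=mirna_id,
                    mrna_id=mrna_id,
                    n_circ_sites=circ_sites[(mirna_id, circ_id)],
                    n_mrna_sites=mrna_sites[(mirna_id, mrna_id)],
                    circ_mrna_r=r,
                    circ_direction=circ_dir,
                    mrna_direction=mrna_dir,
                    mirna_direction=mirna_dir,
                )
            )
    triads.sort(key=lambda t: (-t.score, t.circ_id, t.mirna_id, t.mrna_id))
    return triads


def _called_directions(de: pd.DataFrame) -> dict[str, str]:
    called = de[de["called"]]
    return dict(zip(called["feature_id"], called["direction"]))


def _site_counts(interactions: pd.DataFrame) -> dict[tuple[str, str], int]:
    if interactions.empty:
        return {}
    return {
        (row.mirna_id, row.target_id): int(row.n_sites)
        for row in interactions.itertuples()
    }


_ARROW = {"up": "↑", "down": "↓", None: "?"}


def triads_frame(triads: list[CeRNATriad]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ_id": t.circ_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "n_circ_sites": t.n_circ_sites,
                "n_mrna_sites": t.n_mrna_sites,
                "circ_mrna_r": t.circ_mrna_r,
                "circ_direction": t.circ_direction,
                "mrna_direction": t.mrna_direction,
                "mirna_direction": t.mirna_direction if t.mirna_direction else "",
                "score": t.score,
            }
            for t in triads
        ],
        columns=[
            "circ_id", "mirna_id", "mrna_id", "n_circ_sites", "n_mrna_sites",
            "circ_mrna_r", "circ_direction", "mrna_direction", "mirna_direction",
            "score",
        ],
    )


def triad_report(triads: list[CeRNATriad], path: str | Path) -> pd.DataFrame:
    """Write a TSV of triads plus a mechanism line per triad.

    The mechanism line renders the sponge model, e.g.
    ``circX (down) -| sponge miR-Y (up) -| target GENE (down)``.
    The TSV re-parses to the same triad tuples.
    """
    frame = triads_frame(triads)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    lines_path = path.with_suffix(".mechanism.txt")
    with open(lines_path, "w") as fh:
        fh.write("# ceRNA sponge mechanisms, one per triad\n")
        for t in triads:
            mir_dir = f" ({t.mirna_direction})" if t.mirna_direction else ""
            fh.write(
                f"{t.circ_id} ({t.circ_direction}) -| sponge "
                f"{t.mirna_id}{mir_dir} -| target {t.mrna_id} "
                f"({t.mrna_direction})  [sites circ={t.n_circ_sites} "
                f"mrna={t.n_mrna_sites}, r={t.circ_mrna_r:.3f}]\n"
            )
    return frame
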