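"""Three-tier co-occurrence of methylation with transcript and protein expression.

Joins per-condition gene methylation profiles with differential-expression
calls at the transcript and protein level, then summarizes how often
methylated genes (gene body or 500-bp upstream) are down- or up-regulated,
which genes are traceable at all three levels, and how positional
methylation counts shift between conditions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .expression import DEResult
from .feature_map import GeneMethylationProfile
from .kinetics import MethylomeSummary


@dataclass
class TriLevelRecord:
    locus_tag: str
    #: condition -> profile for this gene (absent condition -> key missing)
    methylation: dict[str, GeneMethylationProfile]
    transcript_de: DEResult | None = None
    protein_de: DEResult | None = None

    def methylated_in(self, condition: str) -> bool:
        prof = self.methylation.get(condition)
        return bool(prof and prof.any_methylation)


@dataclass
class CoOccurrenceSummary:
    treatment: str
    control: str
    n_genes: int
    #: % of the full gene universe methylated in the treatment and transcript down/up
    pct_methylated_down_all_genes: float
    pct_methylated_up_all_genes: float
    #: same numerators over the methylated-gene denominator (published figures are
    #: ambiguous between the two conventions, so both are carried)
    pct_methylated_down_of_methylated: float | None
    pct_methylated_up_of_methylated: float | None
    #: % of genes significant at transcript AND protein level AND methylated
    pct_traceable_all_levels: float
    #: assay -> mod_type -> {"up": fraction, "down": fraction, "n": count} among
    #: methylation-associated DE genes
    up_down_fractions: dict
    #: mod_type -> relative change in positional methylation counts vs control
    methylation_deltas: dict


def build_trilevel(
    profiles_by_condition: Mapping[str, Mapping[str, GeneMethylationProfile]],
    transcript_de: Sequence[DEResult] | None,
    protein_de: Sequence[DEResult] | None,
    locus_tags: Sequence[str],
) -> list[TriLevelRecord]:
    """One record per gene in the annotation universe.

    DE entries for locus tags outside the universe are excluded (returned
    records carry only known genes); genes untested in an assay keep
    ``None`` rather than a zero-effect result.
    """
    universe = list(dict.fromkeys(locus_tags))
    known = set(universe)
    t_map = {r.feature_id: r for r in (transcript_de or []) if r.feature_id in known}
    p_map = {r.feature_id: r for r in (protein_de or []) if r.feature_id in known}
    records = []
    for tag in universe:
        meth = {
            cond: profs[tag]
            for cond, profs in profiles_by_condition.items()
            if tag in profs
        }
        records.append(
            TriLevelRecord(
                locus_tag=tag,
                methylation=meth,
                transcript_de=t_map.get(tag),
                protein_de=p_map.get(tag),
            )
        )
    return records


def unknown_de_features(
    de: Sequence[DEResult], locus_tags: Sequence[str]
) -> list[str]:
    """Locus tags present in DE results but absent from the annotation."""
    known = set(locus_tags)
    return sorted({r.feature_id for r in de if r.feature_id not in known})


def _frac(numer: int, denom: int) -> float | None:
    return numer / denom if denom else None


def co_occurrence_summary(
    records: Sequence[TriLevelRecord],
    treatment: str,
    control: str,
    methylome_treatment: MethylomeSummary | None = None,
    methylome_control: MethylomeSummary | None = None,
) -> CoOccurrenceSummary:
    """Gene-level methylation/expression co-occurrence for one contrast."""
    n_genes = len(records)
    if n_genes == 0:
        raise ValueError("no records")

    def sig_down(r: DEResult | None) -> bool:
        return bool(r and r.significant and r.log2fc < 0)

    def sig_up(r: DEResult | None) -> bool:
        return bool(r and r.significant and r.log2fc > 0)

    meth = [r for r in records if r.methylated_in(treatment)]
    meth_down = sum(1 for r in meth if sig_down(r.transcript_de))
    meth_up = sum(1 for r in meth if sig_up(r.transcript_de))
    traceable = sum(
        1
        for r in meth
        if r.transcript_de and r.transcript_de.significant
        and r.protein_de and r.protein_de.significant
    )

    # Up/down split among methylation-associated DE genes, per assay and mod type
    up_down: dict = {}
    for assay, getter in (("transcriptome", lambda r: r.transcript_de),
                          ("proteome", lambda r: r.protein_de)):
        up_down[assay] = {}
        for mod in ("m6A", "m4C"):
            def has_mod(r: TriLevelRecord) -> bool:
                prof = r.methylation.get(treatment)
                if not prof:
                    return False
                if mod == "m6A":
                    return prof.n_m6A_body + prof.n_m6A_upstream > 0
                return prof.n_m4C_body + prof.n_m4C_upstream > 0

            assoc = [r for r in records if has_mod(r)]
            n_up = sum(1 for r in assoc if sig_up(getter(r)))
            n_down = sum(1 for r in assoc if sig_down(getter(r)))
            n_de = n_up + n_down
            up_down[assay][mod] = {
                "up": _frac(n_up, n_de),
                "down": _frac(n_down, n_de),
                "n": n_de,
            }

    deltas = (
        methylation_deltas(methylome_treatment, methylome_control)
        if methylome_treatment and methylome_control
        else {}
    )
    n_meth = len(meth)
    return CoOccurrenceSummary(
        treatment=treatment,
        control=control,
        n_genes=n_genes,
        pct_methylated_down_all_genes=100 * meth_down / n_genes,
        pct_methylated_up_all_genes=100 * meth_up / n_genes,
        pct_methylated_down_of_methylated=(
            100 * meth_down / n_meth if n_meth else None
        ),
        pct_methylated_up_of_methylated=(
            100 * meth_up / n_meth if n_meth else None
        ),
        pct_traceable_all_levels=100 * traceable / n_genes,
        up_down_fractions=up_down,
        methylation_deltas=deltas,
    )


def methylation_deltas(
    summary_treatment: MethylomeSummary, summary_control: MethylomeSummary
) -> dict:
    """Signed relative change in positional methylation counts, per mod type."""
    out = {}
    for mod, t_count, c_count in (
        ("m6A", summary_treatment.n_m6A, summary_control.n_m6A),
        ("m4C", summary_treatment.n_m4C, summary_control.n_m4C),
    ):
        if c_count == 0:
            out[mod] = {"treatment": t_count, "control": 0, "delta": None,
                        "flag": "undefined_control_zero"}
        else:
            out[mod] = {
                "treatment": t_count,
                "control": c_count,
                "delta": (t_count - c_count) / c_count,
                "flag": "ok",
            }
    return out


# ---------------------------------------------------------------------------
# export


def summary_to_dict(s: CoOccurrenceSummary) -> dict:
    return {
        "treatment": s.treatment,
        "control": s.control,
        "n_genes": s.n_genes,
        "pct_methylated_down_all_genes": s.pct_methylated_down_all_genes,
        "pct_methylated_up_all_genes": s.pct_methylated_up_all_genes,
        "pct_methylated_down_of_methylated": s.pct_methylated_down_of_methylated,
        "pct_methylated_up_of_methylated": s.pct_methylated_up_of_methylated,
        "pct_traceable_all_levels": s.pct_traceable_all_levels,
        "up_down_fractions": s.up_down_fractions,
        "methylation_deltas": s.methylation_deltas,
    }


def write_summary_json(s: CoOccurrenceSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary_to_dict(s), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_summary_tsv(s: CoOccurrenceSummary, path: str | Path) -> None:
    """Flat TSV blocks mirroring an up/down-by-assay-and-mod-type table."""
    rows = []
    for assay, mods in s.up_down_fractions.items():
        for mod, cell in mods.items():
            rows.append(
                {
                    "treatment": s.treatment,
                    "assay": assay,
                    "mod_type": mod,
                    "up_fraction": cell["up"],
                    "down_fraction": cell["down"],
                    "n_de_genes": cell["n"],
                }
            )
    pd.DataFrame(rows).to_csv(str(path), sep="\t", index=False)


def write_circos_track(
    positions_values: Sequence[tuple[int, float]], genome_id: str, path: str | Path
) -> None:
    """Circos-ready per-track text: chr start end value (rendering out of scope)."""
    with open(path, "w") as fh:
        for pos, value in positions_values:
            fh.write(f"{genome_id}\t{pos}\t{pos + 1}\t{value}\n")
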