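"""Missense-variant triage: parsing, tallies, GV/GD annotation and the
one/two/three-predictor damaging vote.

Three predictors are combined per missense variant: SIFT (damaging at
score <= 0.05), PolyPhen (damaging at >= 0.5) and Grantham deviation
(damaging at >= 65, the classical "radical substitution" boundary; all
cutoffs configurable). The number of damaging votes maps to the tiers
none/one/two/three — the green/blue/red classes of a triage scatter plot.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grantham import GranthamTable, grantham_distance, gvgd
from .io import GAP, Alignment, DomevolError, RegionMap, ref_to_column

TIERS = ("none", "one", "two", "three")

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}

_HGVS_RE = re.compile(
    r"^(?:p\.)?(?:\(?)([A-Z][a-z]{2}|[A-Z])(\d+)([A-Z][a-z]{2}|[A-Z])\)?$"
)


@dataclass
class VariantRecord:
    protein_position: int
    ref_aa: str
    alt_aa: str
    variant_class: str = "SNP"
    consequence: str = "missense_variant"
    sift: float | None = None
    polyphen: float | None = None
    gv: float | None = None
    gd: float | None = None
    vote_tier: str | None = None

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise DomevolError("protein_position must be >= 1")
        if self.ref_aa == self.alt_aa:
            raise DomevolError(
                f"ref equals alt ({self.ref_aa}) at {self.protein_position}"
            )
        for score, name, lo, hi in (
            (self.sift, "sift", 0.0, 1.0),
            (self.polyphen, "polyphen", 0.0, 1.0),
        ):
            if score is not None and not lo <= score <= hi:
                raise DomevolError(f"{name} score {score} outside [{lo}, {hi}]")


@dataclass
class VariantSummary:
    n_total: int
    class_counts: pd.Series
    consequence_counts: pd.Series

    @property
    def class_percent(self) -> pd.Series:
        return 100.0 * self.class_counts / max(self.n_total, 1)

    @property
    def top_consequences(self) -> pd.Series:
        return self.consequence_counts.sort_values(ascending=False)


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse 'p.Arg1008Gln', 'Arg1008Gln' or 'R1008Q' -> ('R', 1008, 'Q')."""
    m = _HGVS_RE.match(text.strip())
    if not m:
        raise DomevolError(f"malformed protein change {text!r}")
    ref, pos, alt = m.groups()
    if len(ref) == 3:
        try:
            ref = THREE_TO_ONE[ref]
        except KeyError:
            raise DomevolError(f"unknown residue code {ref!r} in {text!r}") from None
    if len(alt) == 3:
        try:
            alt = THREE_TO_ONE[alt]
        except KeyError:
            raise DomevolError(f"unknown residue code {alt!r} in {text!r}") from None
    return ref, int(pos), alt


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def parse_variants(path, *, on_error: str = "warn") -> list[VariantRecord]:
    """Read a variant TSV into validated records.

    Accepted layouts: a `protein_change` column (HGVS-p or one-letter style),
    or explicit `ref_aa` / `protein_position` / `alt_aa` columns. Optional
    columns: variant_class, consequence, sift, polyphen, gd. Malformed rows
    are rejected and logged (on_error='warn', default) or raised
    (on_error='raise').
    """
    df = pd.read_csv(path, sep="\t")
    records: list[VariantRecord] = []
    n_rejected = 0
    for idx, row in df.iterrows():
        try:
            if "protein_change" in df.columns and not pd.isna(row["protein_change"]):
                ref, pos, alt = parse_protein_change(str(row["protein_change"]))
            else:
                ref, pos, alt = (
                    str(row["ref_aa"]).upper(),
                    int(row["protein_position"]),
                    str(row["alt_aa"]).upper(),
                )
            records.append(
                VariantRecord(
                    protein_position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    variant_class=str(row.get("variant_class", "SNP")),
                    consequence=str(row.get("consequence", "missense_variant")),
                    sift=_opt_float(row.get("sift")),
                    polyphen=_opt_float(row.get("polyphen")),
                    gd=_opt_float(row.get("gd")),
                )
            )
        except (DomevolError, KeyError, ValueError) as exc:
            if on_error == "raise":
                raise DomevolError(f"row {idx}: {exc}") from exc
            n_rejected += 1
            warnings.warn(f"rejected variant row {idx}: {exc}")
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} malformed variant row(s)")
    return records


def write_variants(records: list[VariantRecord], path) -> None:
    pd.DataFrame(
        {
            "protein_change": [f"{r.ref_aa}{r.protein_position}{r.alt_aa}" for r in records],
            "variant_class": [r.variant_class for r in records],
            "consequence": [r.consequence for r in records],
            "sift": [r.sift for r in records],
            "polyphen": [r.polyphen for r in records],
            "gd": [r.gd for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def parse_vcf(path, *, csq_tag: str = "CSQ") -> list[VariantRecord]:
    """Read missense records from a VCF with VEP-style consequence annotation.

    Needs the `CSQ` INFO header declaring subfields including Consequence,
    Protein_position and Amino_acids; SIFT and PolyPhen subfields are parsed
    when present (either bare scores or 'deleterious(0.01)' style).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    raw_desc = ""
    for h in vcf.header_iter():
        info = h.info()
        if info.get("ID") == csq_tag:
            raw_desc = info.get("Description", "")
    m = re.search(r"Format:\s*([^\"']+)", raw_desc)
    if not m:
        raise DomevolError(f"no {csq_tag} Format declaration in VCF header")
    fields = [f.strip() for f in m.group(1).split("|")]
    idx = {f.lower(): i for i, f in enumerate(fields)}
    for needed in ("consequence", "protein_position", "amino_acids"):
        if needed not in idx:
            raise DomevolError(f"{csq_tag} lacks subfield {needed!r}")

    def score_of(parts, key):
        if key not in idx or idx[key] >= len(parts):
            return None
        raw = parts[idx[key]]
        if not raw:
            return None
        m2 = re.search(r"\(([\d.eE+-]+)\)", raw)
        return float(m2.group(1)) if m2 else float(raw)

    records: list[VariantRecord] = []
    for var in vcf:
        csq = var.INFO.get(csq_tag)
        if csq is None:
            continue
        for ann in str(csq).split(","):
            parts = ann.split("|")
            cons = parts[idx["consequence"]]
            if "missense" not in cons:
                continue
            aas = parts[idx["amino_acids"]]
            if "/" not in aas:
                continue
            ref_aa, alt_aa = aas.split("/")[:2]
            pos = int(str(parts[idx["protein_position"]]).split("-")[0].split("/")[0])
            if len(var.REF) == 1 and all(len(a) == 1 for a in var.ALT):
                vclass = "SNP"
            elif all(len(a) > len(var.REF) for a in var.ALT):
                vclass = "insertion"
            elif all(len(a) < len(var.REF) for a in var.ALT):
                vclass = "deletion"
            else:
                vclass = "indel"
            try:
                records.append(
                    VariantRecord(
                        protein_position=pos,
                        ref_aa=ref_aa,
                        alt_aa=alt_aa,
                        variant_class=vclass,
                        consequence=cons,
                        sift=score_of(parts, "sift"),
                        polyphen=score_of(parts, "polyphen"),
                    )
                )
            except DomevolError as exc:
                warnings.warn(f"rejected VCF annotation {ann!r}: {exc}")
    return records


# ---------------------------------------------------------------------------
# scoring and voting


def annotate_gvgd(
    records: list[VariantRecord],
    msa: Alignment,
    reference_id: str,
    table: GranthamTable | None = None,
) -> list[VariantRecord]:
    """Fill gv/gd for each record from its MSA column (alignment-aware).

    Positions whose column carries no residues beyond the reference, or that
    cannot be mapped, fall back to the sequence-only score: GV = 0 and GD =
    the plain Grantham distance between ref and alt.
    """
    for rec in records:
        try:
            col = ref_to_column(msa, reference_id, rec.protein_position)
            observed = [ch for ch in msa.column(col) if ch != GAP and ch != "X"]
        except DomevolError:
            observed = []
        if observed:
            rec.gv, rec.gd = gvgd(observed, rec.alt_aa, table)
        else:
            rec.gv = 0.0
            rec.gd = grantham_distance(rec.ref_aa, rec.alt_aa, table)
    return records


def vote_tier(
    gd: float | None,
    sift: float | None,
    polyphen: float | None,
    *,
    gd_cutoff: float = 65.0,
    sift_cutoff: float = 0.05,
    polyphen_cutoff: float = 0.5,
) -> str:
    """Count of damaging votes mapped to {'none','one','two','three'}.

    Damaging: SIFT <= sift_cutoff, PolyPhen >= polyphen_cutoff,
    GD >= gd_cutoff. Absent scores are non-votes.
    """
    if gd is None and sift is None and polyphen is None:
        raise DomevolError("at least one score must be present")
    votes = 0
    votes += sift is not None and sift <= sift_cutoff
    votes += polyphen is not None and polyphen >= polyphen_cutoff
    votes += gd is not None and gd >= gd_cutoff
    return TIERS[votes]


def assign_tiers(records: list[VariantRecord], **cutoffs) -> list[VariantRecord]:
    for rec in records:
        rec.vote_tier = vote_tier(rec.gd, rec.sift, rec.polyphen, **cutoffs)
    return records


def tier_counts(records: list[VariantRecord]) -> pd.Series:
    counts = pd.Series(0, index=list(TIERS))
    for rec in records:
        if rec.vote_tier is None:
            raise DomevolError("records not tiered; call assign_tiers first")
        counts[rec.vote_tier] += 1
    return counts


def tally(records: list[VariantRecord]) -> VariantSummary:
    """Counts (and hence percentages) by variant class and consequence type."""
    classes = pd.Series([r.variant_class for r in records], dtype=str)
    cons = pd.Series([r.consequence for r in records], dtype=str)
    return VariantSummary(
        n_total=len(records),
        class_counts=classes.value_counts(),
        consequence_counts=cons.value_counts(),
    )


def positional_density(
    records: list[VariantRecord],
    region_map: RegionMap,
    reference_length: int | None = None,
) -> pd.DataFrame:
    """Missense variants per residue for each named region.

    Records outside the reference (when reference_length is given) are
    skipped with a warning count.
    """
    positions = []
    skipped = 0
    for rec in records:
        if reference_length is not None and rec.protein_position > reference_length:
            skipped += 1
            continue
        positions.append(rec.protein_position)
    if skipped:
        warnings.warn(f"skipped {skipped} variant(s) outside the reference")
    pos = np.asarray(positions)
    rows = []
    for region in region_map:
        n = int(((pos >= region.start) & (pos <= region.end)).sum()) if len(pos) else 0
        rows.append(
            {
                "region": region.name,
                "n_missense": n,
                "length": len(region),
                "density": n / len(region),
            }
        )
    return pd.DataFrame(rows)
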