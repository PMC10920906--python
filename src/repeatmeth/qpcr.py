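"""Methylation-sensitive restriction enzyme qPCR and relative expression.

Two molecular readouts of repeat DNA regulation:

* **MSRE-qPCR relative methylation.**  Genomic DNA is digested with a
  methylation-blocked enzyme (AciI, recognition sequence CCGC, non-
  palindromic; a site is CCGC on either strand).  Methylation protects the
  target amplicon, so the surviving template fraction f delays its Ct by
  log_E(1/f) cycles relative to an undigested control amplicon used for
  input normalization.  Relative methylation is E^(−ΔCt) with
  ΔCt = Ct(target) − Ct(control); technical replicates are averaged on the
  Ct scale *before* exponentiation.

* **ΔΔCt relative expression** of repeat transcripts against a reference
  gene (RPLP0 in the assay this mirrors), efficiency-corrected:
  fold = E^(−ΔΔCt).

Amplicon bookkeeping: the target amplicon must contain at least one enzyme
site, the control amplicon none, and neither may contain the
pre-fragmentation site (XbaI, TCTAGA) that would destroy it before
digestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AmpliconSpec",
    "ValidationReport",
    "ACII_MOTIF",
    "XBAI_MOTIF",
    "reverse_complement",
    "count_enzyme_sites",
    "validate_amplicon",
    "msre_relative_methylation",
    "ddct_expression",
    "ASAT_MSRE_PRIMERS",
    "ASAT_CTRL_PRIMERS",
    "ASAT_EXPR_PRIMERS",
    "RPLP0_PRIMERS",
]

ACII_MOTIF = "CCGC"
XBAI_MOTIF = "TCTAGA"

# Published primer pairs of the assay this module mirrors (metadata;
# the genomic amplicons themselves are not bundled).
ASAT_MSRE_PRIMERS = ("CGGACTGCAGTGGCTCAATC", "AAAGAGAGGTTCAGCTGGGC")
ASAT_CTRL_PRIMERS = ("GGATATTTGGACCACTTTGAGGC", "TGGGCGACAGAGCGAGAC")
ASAT_EXPR_PRIMERS = ("CACTCTTTTTGTAGAATCTGC", "AATGCACACATCACAAAGAAG")
RPLP0_PRIMERS = ("CTCTGCATTCTCGCTTCCTGGAG", "CAGATGGATCAGCCAAGAAGG")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_MSRE_ROLES = ("msre_target", "msre_control")
_EXPR_ROLES = ("expr_target", "expr_reference")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_sequence(sequence: str) -> None:
    bad = [i for i, c in enumerate(sequence) if c not in "ACGTN"]
    if bad:
        shown = ", ".join(str(i) for i in bad[:10])
        raise ValueError(
            f"sequence contains {len(bad)} invalid character(s) at position(s) {shown}"
            + ("…" if len(bad) > 10 else "")
        )


def _scan(sequence: str, motif: str, allow_overlap: bool) -> int:
    """Sliding-window motif count (N never matches)."""
    count = 0
    i = 0
    m = len(motif)
    while i <= len(sequence) - m:
        if sequence[i : i + m] == motif:
            count += 1
            i += 1 if allow_overlap else m
        else:
            i += 1
    return count


def count_enzyme_sites(
    sequence: str,
    motif: str = ACII_MOTIF,
    count_both_strands: bool = True,
    allow_overlap: bool = True,
) -> int:
    """Count enzyme recognition sites on the given strand.

    For a non-palindromic motif a site on the opposite strand appears as the
    reverse complement of the motif on the given strand, so both patterns are
    scanned when ``count_both_strands`` is set (a palindromic motif is only
    scanned once).  Overlapping matches count individually when
    ``allow_overlap``.
    """
    _check_sequence(sequence)
    _check_sequence(motif)
    n = _scan(sequence, motif, allow_overlap)
    if count_both_strands:
        rc = reverse_complement(motif)
        if rc != motif:
            n += _scan(sequence, rc, allow_overlap)
    return n


@dataclass(frozen=True)
class AmpliconSpec:
    """A qPCR amplicon with its primers and the enzyme motifs it is scored on."""

    name: str
    sequence: str
    forward_primer: str
    reverse_primer: str
    enzyme_motifs: tuple[str, ...] = (ACII_MOTIF,)


@dataclass
class ValidationReport:
    """Outcome of amplicon validation: individual checks plus site counts."""

    name: str
    ok: bool
    site_count: int
    length: int
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def failures(self) -> list[str]:
        return [msg for _, passed, msg in self.checks if not passed]


def validate_amplicon(spec: AmpliconSpec, role: str | None = None) -> ValidationReport:
    """Check primer presence/orientation and enzyme-site counts for a role.

    ``role='msre_target'`` requires at least one enzyme site,
    ``role='msre_control'`` requires none; any role forbids the XbaI
    pre-fragmentation site inside the amplicon.
    """
    _check_sequence(spec.sequence)
    checks: list[tuple[str, bool, str]] = []

    fwd_ok = spec.forward_primer in spec.sequence
    checks.append(
        ("forward_primer", fwd_ok,
         "ok" if fwd_ok else f"forward primer {spec.forward_primer!r} absent from amplicon")
    )
    rev_ok = reverse_complement(spec.reverse_primer) in spec.sequence
    checks.append(
        ("reverse_primer", rev_ok,
         "ok" if rev_ok else
         f"reverse primer {spec.reverse_primer!r} (as reverse complement) absent from amplicon")
    )

    site_count = sum(
        count_enzyme_sites(spec.sequence, m, count_both_strands=True)
        for m in spec.enzyme_motifs
    )
    if role == "msre_target":
        ok = site_count >= 1
        checks.append(
            ("enzyme_sites", ok,
             "ok" if ok else "target amplicon contains no enzyme site")
        )
    elif role == "msre_control":
        ok = site_count == 0
        checks.append(
            ("enzyme_sites", ok,
             "ok" if ok else
             f"control amplicon must contain no enzyme site but has {site_count}")
        )
    elif role is not None:
        raise ValueError(f"unknown amplicon role {role!r}")

    xbai = count_enzyme_sites(spec.sequence, XBAI_MOTIF, count_both_strands=True)
    checks.append(
        ("no_xbai_site", xbai == 0,
         "ok" if xbai == 0 else
         f"amplicon contains {xbai} XbaI site(s); pre-fragmentation would destroy it")
    )
    return ValidationReport(
        name=spec.name,
        ok=all(passed for _, passed, _ in checks),
        site_count=site_count,
        length=len(spec.sequence),
        checks=checks,
    )


# ---------------------------------------------------------------------------
# relative quantification
# ---------------------------------------------------------------------------


def _mean_ct_by_role(ct_table: pd.DataFrame, roles: tuple[str, str]) -> pd.DataFrame:
    """Average technical replicates on the Ct scale for the two given roles.

    NaN Ct values (undetermined reactions) are ignored in the mean; a
    (condition, repeat, role) cell where *all* replicates are undetermined
    stays NaN.
    """
    required = {"condition", "biological_repeat", "primer_role", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    sub = ct_table[ct_table["primer_role"].isin(roles)]
    means = (
        sub.groupby(["condition", "biological_repeat", "primer_role"])["ct"]
        .mean()  # skips NaN
        .unstack("primer_role")
    )
    for role in roles:
        if role not in means.columns:
            means[role] = np.nan
    return means.reset_index()


def msre_relative_methylation(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Per-repeat relative methylation from an MSRE-qPCR Ct table.

    ΔCt = mean Ct(msre_target) − mean Ct(msre_control) per (condition,
    biological repeat); relative_methylation = efficiency^(−ΔCt), a strictly
    decreasing function of ΔCt that equals the surviving (methylated)
    template fraction under perfect doubling.  With ``reference_condition``
    an additional ``percent_of_reference`` column expresses each repeat
    relative to the same repeat of the reference condition (×100).

    Undetermined target reactions yield ``below_detection=True`` with a NaN
    estimate; a missing or undetermined control is an error.
    """
    if not 1 < efficiency <= 2:
        raise ValueError("efficiency must be in (1, 2]")
    means = _mean_ct_by_role(ct_table, _MSRE_ROLES)
    if means.empty:
        raise ValueError("Ct table contains no MSRE rows")
    if means["msre_control"].isna().any():
        bad = means.loc[means["msre_control"].isna(), ["condition", "biological_repeat"]]
        raise ValueError(
            "missing/undetermined msre_control Ct for: "
            + ", ".join(f"{c}/r{r}" for c, r in bad.itertuples(index=False))
        )
    out = means.rename(columns={"msre_target": "_t", "msre_control": "_c"})
    out["delta_ct"] = out["_t"] - out["_c"]
    out["relative_methylation"] = efficiency ** (-out["delta_ct"])
    out["below_detection"] = out["_t"].isna()
    out = out.drop(columns=["_t", "_c"])

    if reference_condition is not None:
        if reference_condition not in set(out["condition"]):
            raise ValueError(f"reference condition {reference_condition!r} not in table")
        ref = out[out["condition"] == reference_condition].set_index("biological_repeat")[
            "relative_methylation"
        ]
        out["percent_of_reference"] = 100.0 * out["relative_methylation"] / out[
            "biological_repeat"
        ].map(ref)
    return out


def ddct_expression(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    reference_condition: str | None = None,
) -> pd.DataFrame:
    """Per-repeat relative expression by the efficiency-corrected ΔΔCt method.

    ΔCt = mean Ct(expr_target) − mean Ct(expr_reference) per (condition,
    repeat); ΔΔCt subtracts the same repeat's ΔCt in ``reference_condition``;
    fold_change = efficiency^(−ΔΔCt).  Without a reference condition only
    ΔCt and the unnormalized ``relative_expression`` = E^(−ΔCt) are returned.
    """
    if not 1 < efficiency <= 2:
        raise ValueError("efficiency must be in (1, 2]")
    means = _mean_ct_by_role(ct_table, _EXPR_ROLES)
    if means.empty:
        raise ValueError("Ct table contains no expression rows")
    if means["expr_reference"].isna().any():
        bad = means.loc[means["expr_reference"].isna(), ["condition", "biological_repeat"]]
        raise ValueError(
            "missing/undetermined expr_reference Ct for: "
            + ", ".join(f"{c}/r{r}" for c, r in bad.itertuples(index=False))
        )
    out = means.rename(columns={"expr_target": "_t", "expr_reference": "_r"})
    out["delta_ct"] = out["_t"] - out["_r"]
    out["relative_expression"] = efficiency ** (-out["delta_ct"])
    out = out.drop(columns=["_t", "_r"])

    if reference_condition is not None:
        if reference_condition not in set(out["condition"]):
            raise ValueError(f"reference condition {reference_condition!r} not in table")
        ref = out[out["condition"] == reference_condition].set_index("biological_repeat")[
            "delta_ct"
        ]
        out["ddct"] = out["delta_ct"] - out["biological_repeat"].map(ref)
        out["fold_change"] = efficiency ** (-out["ddct"])
    return out
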