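"""96-class mutational-signature profiling.

Single-base substitutions are folded onto the pyrimidine strand and indexed
by (substitution, 5' base, 3' base), giving the standard 96 trinucleotide
classes used throughout the cancer-signature literature (COSMIC v2 layout).
The module provides classification, profile construction, cosine comparison,
transition/transversion summaries, and stage-wise profiling of a variant
table split by VAF and parental evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Class labels in canonical order, e.g. "A[C>A]A", "A[C>A]C", ...
CLASS_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

N_CLASSES = 96

#: Indices of the 32 transition classes (C>T and T>C on the pyrimidine strand).
TRANSITION_CLASSES = frozenset(
    i for i, lab in enumerate(CLASS_LABELS) if lab[2:5] in ("C>T", "T>C")
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT only)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_96(ref: str, alt: str, context: str) -> int:
    """Map a substitution in its trinucleotide context to one of 96 classes.

    Parameters
    ----------
    ref, alt : str
        Single reference and alternate bases.
    context : str
        The 3-mer centred on the mutated position; its middle base must
        equal ``ref``.

    Purine-centred substitutions are mapped to the reverse-complement
    (pyrimidine-centred) representation, so e.g. A>C in AAG and T>G in CTT
    land in the same class.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(ref) != 1 or len(alt) != 1 or len(context) != 3:
        raise ValueError("ref/alt must be single bases and context a 3-mer")
    if any(b not in _COMPLEMENT for b in ref + alt + context):
        raise ValueError(f"non-ACGT character in ({ref}, {alt}, {context})")
    if ref == alt:
        raise ValueError("ref and alt are identical: not a substitution")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref in "AG":  # fold onto the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = revcomp(context)
    sub_idx = SUBSTITUTIONS.index(f"{ref}>{alt}")
    return sub_idx * 16 + BASES.index(context[0]) * 4 + BASES.index(context[2])


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    return {ref.upper(), alt.upper()} in ({"A", "G"}, {"C", "T"})


@dataclass(frozen=True, eq=False)
class SignatureProfile:
    """Normalised weight vector over the 96 substitution classes."""

    weights: np.ndarray
    label: str = ""
    n: int | None = None  # number of mutations the profile was built from

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignatureProfile):
            return NotImplemented
        return (self.label == other.label and self.n == other.n
                and np.array_equal(self.weights, other.weights))

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} weights, got {w.shape}")
        if (w < 0).any():
            raise ValueError("signature weights must be non-negative")
        if not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"signature weights sum to {w.sum()}, not 1")
        object.__setattr__(self, "weights", w)

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(CLASS_LABELS), name=self.label)


def profile(snvs: pd.DataFrame, label: str = "") -> SignatureProfile:
    """Empirical 96-class profile of a variant table.

    ``snvs`` needs columns ``ref``, ``alt``, ``context``. Raises on empty
    input — an all-zero profile is not a signature.
    """
    if len(snvs) == 0:
        raise ValueError("cannot profile an empty variant set")
    counts = np.zeros(N_CLASSES)
    for ref, alt, ctx in zip(snvs["ref"], snvs["alt"], snvs["context"]):
        counts[classify_96(ref, alt, ctx)] += 1
    return SignatureProfile(counts / counts.sum(), label=label, n=len(snvs))


def cosine(p: SignatureProfile | np.ndarray, q: SignatureProfile | np.ndarray) -> float:
    """Cosine similarity between two non-negative profiles, in [0, 1]."""
    a = p.weights if isinstance(p, SignatureProfile) else np.asarray(p, float)
    b = q.weights if isinstance(q, SignatureProfile) else np.asarray(q, float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for an all-zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def tstv(snvs: pd.DataFrame) -> tuple[float, int, int]:
    """Transversion/transition ratio and the two counts.

    Returns ``(tv/ts, n_ts, n_tv)``; the ratio is ``inf`` when there are
    transversions but no transitions, and ``nan`` for an empty table.
    """
    if len(snvs) == 0:
        return (float("nan"), 0, 0)
    ts = int(sum(is_transition(r, a) for r, a in zip(snvs["ref"], snvs["alt"])))
    tv = len(snvs) - ts
    if ts == 0:
        return (float("inf") if tv else float("nan"), ts, tv)
    return (tv / ts, ts, tv)


# ---------------------------------------------------------------------------
# Stage partition (pre-existing / early de novo / prolonged culture)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageBounds:
    """VAF boundaries for the stage partition of de novo SNVs.

    Defaults follow the figure-caption convention: stage 2 (reprogramming-
    associated de novo) spans 1-25% VAF, stage 3 (prolonged culture) is
    below 1%, and the clone-wide set sits in a window around 50%.
    """

    stage2: tuple[float, float] = (0.01, 0.25)
    stage3_max: float = 0.01
    fifty_pct: tuple[float, float] = (0.35, 0.65)
    parental_min_alt: int = 2  # parental evidence => pre-existing (stage 1)


def assign_stages(
    snvs: pd.DataFrame, bounds: StageBounds = StageBounds()
) -> pd.Series:
    """Label each SNV 'stage1' / 'stage2' / 'stage3' / 'fifty_pct' / 'other'.

    ``snvs`` needs a ``vaf`` column; a ``parental_alt`` column (alt reads in
    the parental somatic sample) triggers the stage-1 rule when present.
    """
    labels = []
    parental = snvs["parental_alt"] if "parental_alt" in snvs.columns else None
    for i, vaf in enumerate(snvs["vaf"]):
        if parental is not None and parental.iloc[i] >= bounds.parental_min_alt:
            labels.append("stage1")
        elif bounds.fifty_pct[0] <= vaf <= bounds.fifty_pct[1]:
            labels.append("fifty_pct")
        elif bounds.stage2[0] <= vaf <= bounds.stage2[1]:
            labels.append("stage2")
        elif vaf < bounds.stage3_max:
            labels.append("stage3")
        else:
            labels.append("other")
    return pd.Series(labels, index=snvs.index, name="stage")


def stage_profiles(
    snvs: pd.DataFrame,
    references: list[SignatureProfile],
    bounds: StageBounds = StageBounds(),
    min_n: int = 5,
) -> tuple[dict[str, SignatureProfile], pd.DataFrame]:
    """Per-stage 96-class profiles and their cosine table against references.

    Returns ``(profiles, table)`` where ``table`` has one row per stage with
    at least ``min_n`` SNVs, one cosine column per reference label, plus
    ``n`` and ``top_match`` columns.
    """
    if not references:
        raise ValueError("at least one reference signature is required")
    stages = assign_stages(snvs, bounds)
    profiles: dict[str, SignatureProfile] = {}
    rows = {}
    for stage in ("stage1", "fifty_pct", "stage2", "stage3"):
        sub = snvs[stages == stage]
        if len(sub) < min_n:
            continue
        prof = profile(sub, label=stage)
        profiles[stage] = prof
        sims = {r.label: cosine(prof, r) for r in references}
        rows[stage] = {**sims, "n": len(sub),
                       "top_match": max(sims, key=sims.get)}
    return profiles, pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Bundled synthetic reference signatures and CSV I/O
# ---------------------------------------------------------------------------

def _normalized(w: np.ndarray, label: str) -> SignatureProfile:
    return SignatureProfile(w / w.sum(), label=label)


def signature_17_like() -> SignatureProfile:
    """Synthetic stand-in for the T>G-at-NTT cancer signature.

    Concentrates 80% of its mass on the four T>G classes with a 3' T
    (ATT, CTT, GTT, TTT contexts) and spreads the rest thinly; it is a
    constructed fixture, not a catalogue signature.
    """
    w = np.full(N_CLASSES, 0.2 / 92)
    for i, lab in enumerate(CLASS_LABELS):
        if lab[2:5] == "T>G" and lab[6] == "T":
            w[i] = 0.2
    return _normalized(w, "Sig17-like (synthetic)")


def signature_18_like() -> SignatureProfile:
    """Synthetic C>A-dominated profile mimicking an 8-oxoG-driven signature."""
    w = np.full(N_CLASSES, 0.25 / 80)
    for i, lab in enumerate(CLASS_LABELS):
        if lab[2:5] == "C>A":
            w[i] = 0.75 / 16
    return _normalized(w, "Sig18-like (synthetic)")


def background_signature() -> SignatureProfile:
    """Transition-biased background profile for spontaneous culture mutations.

    90% of mass uniform over the 32 transition classes (C>T, T>C), 10% over
    the transversions; synthetic, used as the simulator's default background.
    """
    w = np.full(N_CLASSES, 0.1 / 64)
    for i in TRANSITION_CLASSES:
        w[i] = 0.9 / 32
    return _normalized(w, "background (synthetic)")


def read_signature_csv(path) -> list[SignatureProfile]:
    """Read reference signatures from a CSV in COSMIC v2 layout.

    Expects 96 rows with columns ``SubType`` (e.g. ``C>A``), ``Trinucleotide``
    (e.g. ``ACA``) and one numeric column per signature.
    """
    df = pd.read_csv(path)
    required = {"SubType", "Trinucleotide"}
    if not required.issubset(df.columns):
        raise ValueError(f"signature CSV must have columns {sorted(required)}")
    if len(df) != N_CLASSES:
        raise ValueError(f"expected {N_CLASSES} rows, got {len(df)}")
    idx = [
        SUBSTITUTIONS.index(sub) * 16 + BASES.index(tri[0]) * 4 + BASES.index(tri[2])
        for sub, tri in zip(df["SubType"], df["Trinucleotide"])
    ]
    if sorted(idx) != list(range(N_CLASSES)):
        raise ValueError("signature CSV does not cover the 96 classes exactly once")
    sigs = []
    for col in df.columns:
        if col in required:
            continue
        w = np.zeros(N_CLASSES)
        w[idx] = df[col].to_numpy(float)
        sigs.append(_normalized(w, str(col)))
    return sigs


def write_signature_csv(path, signatures: list[SignatureProfile]) -> None:
    """Write profiles in the same COSMIC v2 CSV layout `read_signature_csv` reads."""
    out = pd.DataFrame(
        {
            "SubType": [lab[2:5] for lab in CLASS_LABELS],
            "Trinucleotide": [lab[0] + lab[2] + lab[6] for lab in CLASS_LABELS],
        }
    )
    for sig in signatures:
        out[sig.label or "signature"] = sig.weights
    out.to_csv(path, index=False)
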