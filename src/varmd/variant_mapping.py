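"""Map catalogued missense variants onto protein structures.

This module covers the variant-to-model stage of the pipeline: parsing
"p.Arg229Gln"-style protein changes from somatic-mutation tables (COSMIC
snapshots), aligning the catalogue's reference isoform against the sequence
actually present in the crystal structure, sampling a reproducible subset of
variants, and emitting single-mutation structure models with the mutated side
chain truncated to Cβ (rotamer rebuilding is delegated to downstream
modelling tools).

The isoform problem is handled generically: catalogues may number variants on
a different isoform than the structure (for OGG1, the mitochondrial 2a vs. the
nuclear 1a), so positions are transferred through a global Needleman–Wunsch
alignment and the identity of the reference residue is always re-checked
against the structure.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .residues import AA1_TO_3, AA3_TO_1, BACKBONE_KEEP, is_amino_acid
from .structures import ResidueKey, StructureModel, write_pdb

__all__ = [
    "VariantRecord",
    "SequenceAlignmentMap",
    "ProteinChangeError",
    "NotMissenseError",
    "ReferenceMismatchError",
    "parse_protein_change",
    "load_variant_table",
    "build_alignment_map",
    "structure_sequence",
    "map_variant",
    "sample_variants",
    "mutate_structure",
    "kabsch_superpose",
    "write_variant_models",
]

log = logging.getLogger(__name__)


class ProteinChangeError(ValueError):
    """Malformed protein-change string."""


class NotMissenseError(ProteinChangeError):
    """Well-formed protein change that is not a missense substitution."""


class ReferenceMismatchError(ValueError):
    """Variant reference residue disagrees with the structure."""


@dataclass(frozen=True)
class VariantRecord:
    """One missense substitution in reference-isoform numbering."""

    gene: str
    aa_ref: str
    aa_pos: int
    aa_alt: str
    source_id: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.aa_ref not in AA1_TO_3 or self.aa_alt not in AA1_TO_3:
            raise ValueError(f"unknown amino acid in {self.aa_ref}/{self.aa_alt}")
        if self.aa_ref == self.aa_alt:
            raise NotMissenseError(f"{self.aa_ref}{self.aa_pos}{self.aa_alt}: synonymous")
        if self.aa_pos < 1:
            raise ValueError("aa_pos must be 1-based (>= 1)")

    @property
    def label(self) -> str:
        return f"{self.aa_ref}{self.aa_pos}{self.aa_alt}"


_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Za-z]{1,3})(\d+)(.+)$")


def _decode_residue(token: str, context: str) -> str:
    token = token.strip()
    if len(token) == 1 and token.upper() in AA1_TO_3:
        return token.upper()
    if len(token) == 3 and token.upper() in AA3_TO_1:
        return AA3_TO_1[token.upper()]
    raise ProteinChangeError(f"{context}: unrecognized residue code {token!r}")


def parse_protein_change(text: str) -> tuple[str, int, str]:
    """Parse a missense protein change like ``p.I145M`` or ``p.Arg229Gln``.

    Returns ``(aa_ref, aa_pos, aa_alt)`` in one-letter codes.  Non-missense
    changes (nonsense, frameshift, deletions, synonymous) raise
    :class:`NotMissenseError`; anything unparseable raises
    :class:`ProteinChangeError`.
    """
    text = text.strip()
    m = _CHANGE_RE.match(text)
    if not m:
        raise ProteinChangeError(f"cannot parse protein change {text!r}")
    ref_tok, pos_tok, alt_tok = m.groups()
    alt_tok = alt_tok.strip()
    low = alt_tok.lower()
    if low in ("*", "ter", "x") or alt_tok.endswith("*"):
        raise NotMissenseError(f"{text!r}: nonsense change")
    if "fs" in low:
        raise NotMissenseError(f"{text!r}: frameshift")
    if low in ("=",) or any(tag in low for tag in ("del", "ins", "dup")):
        raise NotMissenseError(f"{text!r}: not a substitution")
    aa_ref = _decode_residue(ref_tok, text)
    aa_alt = _decode_residue(alt_tok, text)
    if aa_ref == aa_alt:
        raise NotMissenseError(f"{text!r}: synonymous (ref equals alt)")
    return aa_ref, int(pos_tok), aa_alt


_CHANGE_COLUMNS = ("Mutation AA", "MUTATION_AA", "protein_change", "AA_Mutation",
                   "aa_change", "HGVSP")
_GENE_COLUMNS = ("Gene name", "GENE_SYMBOL", "gene", "Gene")
_ID_COLUMNS = ("Mutation ID", "GENOMIC_MUTATION_ID", "LEGACY_MUTATION_ID", "id")


def _pick_column(df: pd.DataFrame, explicit: str | None, candidates) -> str | None:
    if explicit is not None:
        if explicit not in df.columns:
            raise KeyError(f"column {explicit!r} not present in table")
        return explicit
    for c in candidates:
        if c in df.columns:
            return c
    return None


def load_variant_table(
    path,
    gene: str,
    *,
    change_column: str | None = None,
    gene_column: str | None = None,
    id_column: str | None = None,
    sep: str = "\t",
) -> list[VariantRecord]:
    """Load all parseable missense variants for ``gene`` from a local
    catalogue snapshot (TSV).

    Records are deduplicated on ``(aa_ref, aa_pos, aa_alt)``; non-missense
    rows are counted and logged, never fatal.
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    change_col = _pick_column(df, change_column, _CHANGE_COLUMNS)
    if change_col is None:
        raise KeyError(
            f"no protein-change column found (looked for {_CHANGE_COLUMNS}); "
            "pass change_column explicitly"
        )
    gene_col = _pick_column(df, gene_column, _GENE_COLUMNS)
    id_col = _pick_column(df, id_column, _ID_COLUMNS)
    if gene_col is not None:
        df = df[df[gene_col].str.split("_").str[0] == gene]
    records: dict[tuple[str, int, str], VariantRecord] = {}
    skipped = 0
    for _, row in df.iterrows():
        try:
            aa_ref, aa_pos, aa_alt = parse_protein_change(row[change_col])
        except NotMissenseError as exc:
            skipped += 1
            log.info("skipping non-missense row: %s", exc)
            continue
        except ProteinChangeError as exc:
            skipped += 1
            log.warning("skipping unparseable row: %s", exc)
            continue
        key = (aa_ref, aa_pos, aa_alt)
        if key not in records:
            records[key] = VariantRecord(
                gene=gene,
                aa_ref=aa_ref,
                aa_pos=aa_pos,
                aa_alt=aa_alt,
                source_id=str(row[id_col]) if id_col else "",
                annotation="",
            )
    if skipped:
        log.info("%d non-missense/unparseable rows skipped", skipped)
    if not records:
        log.warning("no missense records found for gene %s", gene)
    return list(records.values())


@dataclass(frozen=True)
class SequenceAlignmentMap:
    """Matched 1-based positions between a reference isoform and a target
    sequence; positions aligned to gaps are simply absent."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        last = (0, 0)
        for p in self.pairs:
            if p[0] <= last[0] or p[1] <= last[1]:
                raise ValueError("alignment map must be strictly increasing")
            last = p

    def ref_to_target(self, ref_pos: int) -> int | None:
        for r, t in self.pairs:
            if r == ref_pos:
                return t
        return None


def build_alignment_map(ref_seq: str, target_seq: str) -> SequenceAlignmentMap:
    """Global Needleman–Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5)
    between the catalogue's reference isoform and the structure's sequence."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(ref_seq, target_seq)[0]
    pairs: list[tuple[int, int]] = []
    for (r0, r1), (t0, t1) in zip(*aln.aligned):
        for off in range(r1 - r0):
            pairs.append((r0 + off + 1, t0 + off + 1))
    return SequenceAlignmentMap(tuple(pairs))


def structure_sequence(
    model: StructureModel, chain_id: str | None = None
) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of the structure's amino-acid residues (authored
    order) and the residue keys backing each position."""
    seq: list[str] = []
    keys: list[ResidueKey] = []
    for key in model.residue_keys():
        if chain_id is not None and key[0] != chain_id:
            continue
        name = model.residue_name(key)
        if is_amino_acid(name):
            seq.append(AA3_TO_1[name])
            keys.append(key)
    return "".join(seq), keys


def map_variant(
    v: VariantRecord,
    iso_map: SequenceAlignmentMap,
    struct_positions: list[tuple[ResidueKey, str]],
) -> ResidueKey | None:
    """Transfer a variant position onto the structure.

    ``struct_positions`` lists (residue key, one-letter code) in the order of
    the alignment's target sequence.  Returns the structure residue key, or
    ``None`` when the position fell on an alignment gap (e.g. a disordered
    residue absent from the model).  A residue-identity mismatch raises
    :class:`ReferenceMismatchError` — it signals numbering drift, not a gap.
    """
    t_pos = iso_map.ref_to_target(v.aa_pos)
    if t_pos is None:
        return None
    if not 1 <= t_pos <= len(struct_positions):
        return None
    key, one = struct_positions[t_pos - 1]
    if one != v.aa_ref:
        raise ReferenceMismatchError(
            f"{v.label}: structure has {one} at mapped position "
            f"{key}, expected {v.aa_ref}"
        )
    return key


def sample_variants(records: list[VariantRecord], k: int, seed: int) -> list[VariantRecord]:
    """Uniform sample of ``k`` distinct records without replacement.

    The selection is a pure function of the record *set* (input order is
    normalized away), ``k`` and ``seed``.
    """
    if k > len(records):
        raise ValueError(f"cannot sample {k} of {len(records)} records")
    ordered = sorted(records, key=lambda r: (r.aa_pos, r.aa_ref, r.aa_alt))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=k, replace=False)
    return [ordered[i] for i in sorted(idx)]


def mutate_structure(
    model: StructureModel, site: ResidueKey, aa_alt: str
) -> StructureModel:
    """Introduce a single substitution by renaming the residue and truncating
    its side chain to Cβ (to CA for a glycine target).  Every other atom is
    carried over untouched."""
    site = tuple(site)
    if len(site) == 2:
        site = (site[0], site[1], "")
    table = model.residue_table
    if site not in table:
        raise KeyError(f"residue {site} not present in model")
    old_name = model.residue_name(site)
    if not is_amino_acid(old_name):
        raise TypeError(f"residue {site} is {old_name}, not a standard amino acid")
    new_name = AA1_TO_3[aa_alt]
    keep = set(BACKBONE_KEEP)
    if new_name == "GLY":
        keep.discard("CB")
    site_idx = set(table[site])
    atoms = []
    rows = []
    for i, a in enumerate(model.atoms):
        if i in site_idx:
            if a.name not in keep:
                continue
            a = replace(a, res_name=new_name)
        atoms.append(a)
        rows.append(i)
    return StructureModel(atoms, model.coords[rows])


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of matched point sets (Kabsch).

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) and ``t``
    a translation such that ``coords_a @ R.T + t`` minimizes the RMSD to
    ``coords_b``.  A reflection-only optimum is sign-corrected so the result
    is always a rotation.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"matched (n, 3) point sets required, got {A.shape} vs {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("at least 3 points required")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    sv = np.linalg.svd(A0, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) point set")
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A0 @ R.T - B0
    rmsd = float(np.sqrt((diff**2).sum() / A.shape[0]))
    return R, t, rmsd


def write_variant_models(
    model: StructureModel,
    variants: list[VariantRecord],
    sites: dict[str, ResidueKey | None],
    out_dir,
    *,
    gene: str,
    seed: int,
) -> dict:
    """Emit one PDB per mapped variant plus a JSON manifest recording the
    seed, the mapping table and any skipped records."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"gene": gene, "seed": seed, "rng": "numpy PCG64", "models": [],
                "unmapped": []}
    for v in variants:
        site = sites.get(v.label)
        if site is None:
            manifest["unmapped"].append(v.label)
            continue
        mutated = mutate_structure(model, site, v.aa_alt)
        fname = f"{gene}_{v.label}.pdb"
        write_pdb(mutated, out / fname)
        manifest["models"].append(
            {"variant": v.label, "file": fname,
             "site": {"chain": site[0], "residue": site[1], "icode": site[2]}}
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
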