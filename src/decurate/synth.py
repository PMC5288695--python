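"""Synthetic transcriptome generator with a complete ground-truth manifest.

Emulates the inputs of a post-assembly curation study of an injury time
course: contigs carrying planted ORFs in three homology classes
(annotated in the reference proteome, conserved only among comparator
species, or no ORF at all), planted assembly anomalies (near-duplicate
redundancy, fragmented transcripts, retained GT...AG introns, single-base
frameshifts, contaminants), and NB-distributed counts over a
4-time-point x 3-replicate design with six expression-profile archetypes.

Every contig is recorded in a manifest so downstream stages can be tested
against planted truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .orfs import max_stopfree_run
from . import io as dio

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, standard code (for uniform reverse translation)
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tab  # noqa: E402

for _codon, _aa in _tab.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(_tab.stop_codons)

#: Default per-time-point log2 offsets from baseline for the six profile
#: archetypes (time points 0, 3, 20, 96 hps): sustained early induction,
#: transient early induction overshooting on return, induction at 20 hps
#: resolving by 96 hps, and the three mirror-image repression shapes.
#: After mean-centring these six profiles are three orthogonal contrasts
#: and their negatives — the maximally separable arrangement under the
#: correlation distance used for subclustering (six mutually positively
#: correlated shapes cannot be told apart at a fixed dendrogram cut).
DEFAULT_ARCHETYPES: dict[int, tuple[float, float, float, float]] = {
    1: (0.0, 4.0, 4.0, 4.0),
    2: (0.0, 4.0, -2.0, -2.0),
    3: (0.0, 0.0, 4.0, -4.0),
    4: (0.0, -4.0, -4.0, -4.0),
    5: (0.0, -4.0, 2.0, 2.0),
    6: (0.0, 0.0, -4.0, 4.0),
}


@dataclass
class SimDesign:
    """Parameters of the simulated study.

    Defaults mirror a regeneration time course: samples at 0, 3, 20 and
    96 hours post sectioning with three replicates, moderately dispersed
    NB counts, and clearly separated planted fold changes (|log2| = 4 at
    active time points) so threshold behaviour is testable.
    """

    timepoints: tuple[int, ...] = (0, 3, 20, 96)
    replicates: int = 3
    n_contigs: int = 600
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    dispersion: float = 0.2
    archetypes: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    de_fraction: float = 0.5
    baseline_fpkm_range: tuple[float, float] = (20.0, 200.0)
    # contig class fractions (annotated, conserved_uncharacterised, no_orf,
    # contaminant); roughly the composition reported for curated DE contigs
    # in de novo assemblies of non-model species
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "annotated": 0.22,
            "conserved_uncharacterised": 0.20,
            "no_orf": 0.575,
            "contaminant": 0.005,
        }
    )
    anomaly_rates: dict[str, float] = field(
        default_factory=lambda: {
            "redundant": 0.04,
            "fragment_pair": 0.04,
            "intron_retained": 0.02,
            "frameshifted": 0.02,
        }
    )
    protein_length_range: tuple[int, int] = (60, 300)
    utr_length_range: tuple[int, int] = (30, 150)
    noncoding_length_range: tuple[int, int] = (250, 800)
    comparator_divergence: float = 0.2
    n_comparators: int = 2
    min_orf_aa: int = 33
    prior_assembly_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per time point")
        if min(self.library_size_range) <= 0:
            raise ValueError("library sizes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"hps{tp}_r{r}", "timepoint_hps": tp, "replicate": r}
            for tp in self.timepoints
            for r in range(1, self.replicates + 1)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------

def simulate_proteome(
    n: int,
    length_range: tuple[int, int] = (60, 300),
    seed: int | np.random.Generator = 0,
    prefix: str = "prot",
) -> dict[str, str]:
    """``n`` random proteins over the 20-aa alphabet, each starting with M."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = length_range
    out = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        body = "".join(rng.choice(list(AA_ALPHABET), size=length - 1))
        out[f"{prefix}{i:05d}"] = "M" + body
    return out


def diverge_proteome(
    proteins: dict[str, str],
    divergence_rate: float,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Substitute each site with probability ``divergence_rate``.

    Substitutions always change the residue, so expected identity to the
    source is 1 - rate.  Number and order of proteins are preserved.
    """
    if not 0 <= divergence_rate < 1:
        raise ValueError("divergence rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = {}
    for name, seq in proteins.items():
        chars = list(seq)
        hits = np.nonzero(rng.random(len(chars)) < divergence_rate)[0]
        for i in hits:
            choices = [a for a in AA_ALPHABET if a != chars[i]]
            chars[i] = choices[int(rng.integers(len(choices)))]
        out[name] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------

def reverse_translate(aa: str, rng: np.random.Generator, stop: bool = True) -> str:
    """Reverse-translate with uniform codon choice; optionally append a stop."""
    codons = [_CODONS[a][int(rng.integers(len(_CODONS[a])))] for a in aa]
    if stop:
        codons.append(_STOPS[int(rng.integers(len(_STOPS)))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _first_long_run(seq: str, min_aa: int):
    """Locate one stop-free codon run >= min_aa in any of the six frames."""
    from .orfs import translate

    for strand in ("+", "-"):
        for frame in (0, 1, 2):
            pos = 0
            for seg in translate(seq, frame, strand).split("*"):
                if len(seg) >= min_aa:
                    return strand, frame, pos, pos + len(seg)
                pos += len(seg) + 1
    return None


def make_noncoding(
    rng: np.random.Generator, length: int, min_aa: int = 33, max_iter: int = 400
) -> str:
    """A random sequence certified to contain no ORF >= ``min_aa`` in any
    frame or mode (no stop-free codon run that long, forward or reverse)."""
    seq = list(_random_nt(rng, length))
    for _ in range(max_iter):
        hit = _first_long_run("".join(seq), min_aa)
        if hit is None:
            break
        strand, frame, c0, c1 = hit
        # random position near the middle: deterministic midpoint repair can
        # oscillate when runs on opposite strands overlap the same bases
        lo = c0 + (c1 - c0) // 4
        hi = max(lo + 1, c1 - (c1 - c0) // 4)
        codon = int(rng.integers(lo, hi))
        stop = _STOPS[int(rng.integers(len(_STOPS)))]
        if strand == "+":
            p = frame + 3 * codon
            seq[p : p + 3] = list(stop)
        else:
            p_rev = frame + 3 * codon
            p = length - (p_rev + 3)
            from Bio.Seq import reverse_complement

            seq[p : p + 3] = list(reverse_complement(stop))
    result = "".join(seq)
    if max_stopfree_run(result) >= min_aa:
        raise RuntimeError("failed to scrub ORFs from non-coding contig")
    return result


@dataclass
class SyntheticDataset:
    """All inputs of one simulated study plus its truth manifest."""

    contigs: dict[str, str]
    ref_proteome: dict[str, str]
    comparator_proteomes: dict[str, dict[str, str]]
    decoy_db: dict[str, str]
    prior_assembly: dict[str, str]
    manifest: pd.DataFrame  # one row per contig
    design: SimDesign
    sheet: pd.DataFrame | None = None  # sample sheet incl. true library sizes

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_fasta(self.contigs, outdir / "contigs.fasta")
        dio.write_fasta(self.ref_proteome, outdir / "reference_proteome.fasta")
        for name, db in self.comparator_proteomes.items():
            dio.write_fasta(db, outdir / f"comparator_{name}.fasta")
        dio.write_fasta(self.decoy_db, outdir / "decoys.fasta")
        dio.write_fasta(self.prior_assembly, outdir / "prior_assembly.fasta")
        self.manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest.to_dict(orient="records"), fh, indent=1)
        sheet = self.sheet if self.sheet is not None else self.design.sample_sheet()
        dio.write_sample_sheet(sheet, outdir / "samples.csv")

    @classmethod
    def read(cls, outdir: str | Path, design: SimDesign) -> "SyntheticDataset":
        outdir = Path(outdir)
        comparators = {}
        for p in sorted(outdir.glob("comparator_*.fasta")):
            comparators[p.stem.removeprefix("comparator_")] = dio.read_fasta(p)
        manifest = pd.read_csv(outdir / "manifest.tsv", sep="\t", keep_default_na=False)
        return cls(
            contigs=dio.read_fasta(outdir / "contigs.fasta"),
            ref_proteome=dio.read_fasta(outdir / "reference_proteome.fasta"),
            comparator_proteomes=comparators,
            decoy_db=dio.read_fasta(outdir / "decoys.fasta"),
            prior_assembly=dio.read_fasta(outdir / "prior_assembly.fasta"),
            manifest=manifest,
            design=design,
        )


def _manifest_row(
    contig_id: str,
    klass: str,
    orf_span: tuple[int, int] | None,
    anomaly: str = "none",
    archetype: int = 0,
    parent_sequence: str = "",
    homolog_id: str = "",
) -> dict:
    return {
        "contig_id": contig_id,
        "class_label": klass,
        "orf_start": orf_span[0] if orf_span else -1,
        "orf_end": orf_span[1] if orf_span else -1,
        "anomaly": anomaly,
        "archetype": archetype,
        "parent_sequence": parent_sequence,
        "homolog_id": homolog_id,
    }


def simulate_transcripts(
    ref_proteome: dict[str, str],
    lineage_proteome: dict[str, str],
    design: SimDesign,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build the contig set and its truth manifest.

    Annotated contigs reverse-translate reference proteins; conserved-
    uncharacterised contigs reverse-translate lineage proteins (present
    only in the comparator proteomes the orchestrator derives from them);
    no-ORF contigs are certified free of any ORF >= the minimum length at
    generation time.  Anomalies are planted afterwards on eligible coding
    contigs at the configured rates.
    """
    if not ref_proteome:
        raise ValueError("reference proteome is empty")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    fr = design.class_fractions
    n = design.n_contigs
    labels = rng.choice(
        list(fr), size=n, p=np.array([fr[k] for k in fr]) / sum(fr.values())
    )

    contigs: dict[str, str] = {}
    rows: list[dict] = []
    ref_ids = sorted(ref_proteome)
    lineage_ids = sorted(lineage_proteome)
    u_lo, u_hi = design.utr_length_range

    for i, klass in enumerate(labels):
        cid = f"contig{i:05d}"
        if klass in ("annotated", "conserved_uncharacterised"):
            pool, pool_ids = (
                (ref_proteome, ref_ids) if klass == "annotated" else (lineage_proteome, lineage_ids)
            )
            pid = pool_ids[int(rng.integers(len(pool_ids)))]
            orf_nt = reverse_translate(pool[pid], rng)
            utr5 = _random_nt(rng, int(rng.integers(u_lo, u_hi + 1)))
            utr3 = _random_nt(rng, int(rng.integers(u_lo, u_hi + 1)))
            seq = utr5 + orf_nt + utr3
            span = (len(utr5), len(utr5) + len(orf_nt))
            contigs[cid] = seq
            rows.append(_manifest_row(cid, klass, span, homolog_id=pid))
        elif klass == "no_orf":
            lo, hi = design.noncoding_length_range
            seq = make_noncoding(rng, int(rng.integers(lo, hi + 1)), design.min_orf_aa)
            contigs[cid] = seq
            rows.append(_manifest_row(cid, "no_orf", None))
        else:  # contaminant: planted copy of a decoy entry (filled in later)
            contigs[cid] = ""  # placeholder, replaced by the orchestrator
            rows.append(_manifest_row(cid, "contaminant", None, anomaly="contaminant"))

    manifest = pd.DataFrame(rows)
    manifest = _plant_anomalies(contigs, manifest, design, rng)
    return contigs, manifest


def _mutate_nt(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = choices[int(rng.integers(3))]
    return "".join(chars)


def _plant_anomalies(
    contigs: dict[str, str], manifest: pd.DataFrame, design: SimDesign, rng: np.random.Generator
) -> pd.DataFrame:
    coding = manifest.index[
        manifest["class_label"].isin(["annotated", "conserved_uncharacterised"])
    ].to_numpy()
    rng.shuffle(coding)
    rates = design.anomaly_rates
    n = len(manifest)
    quotas = {kind: int(round(rates.get(kind, 0.0) * n)) for kind in rates}
    pos = 0

    def take(k: int) -> list[int]:
        nonlocal pos
        got = list(coding[pos : pos + k])
        pos += len(got)
        return got

    new_contigs: dict[str, str] = {}
    new_rows: list[dict] = []
    drop: list[str] = []

    # near-duplicates: extra copies at >= 96% identity sharing the parent's profile
    for idx in take(quotas.get("redundant", 0)):
        parent = manifest.at[idx, "contig_id"]
        dup_id = f"{parent}_dup"
        new_contigs[dup_id] = _mutate_nt(contigs[parent], 0.02, rng)
        row = dict(manifest.loc[idx])
        row.update(contig_id=dup_id, anomaly=f"redundant_of:{parent}")
        new_rows.append(row)

    # fragment pairs: the parent is replaced by two overlapping fragments
    for idx in take(quotas.get("fragment_pair", 0)):
        parent = manifest.at[idx, "contig_id"]
        seq = contigs[parent]
        if len(seq) < 200:
            continue
        overlap = int(rng.integers(25, 61))
        cut = int(rng.integers(len(seq) // 3, 2 * len(seq) // 3))
        a_id, b_id = f"{parent}_fragA", f"{parent}_fragB"
        new_contigs[a_id] = seq[: cut + overlap]
        new_contigs[b_id] = seq[cut:]
        for fid, other in ((a_id, b_id), (b_id, a_id)):
            row = dict(manifest.loc[idx])
            row.update(
                contig_id=fid,
                anomaly=f"fragment_pair:{other}",
                parent_sequence=seq,
                orf_start=-1,
                orf_end=-1,
            )
            new_rows.append(row)
        drop.append(parent)

    # intron retention: GT...AG insert at a codon boundary inside the ORF
    for idx in take(quotas.get("intron_retained", 0)):
        parent = manifest.at[idx, "contig_id"]
        seq = contigs[parent]
        s, e = int(manifest.at[idx, "orf_start"]), int(manifest.at[idx, "orf_end"])
        n_codons = (e - s) // 3
        if n_codons < 70:
            continue
        at_codon = int(rng.integers(int(0.4 * n_codons), int(0.6 * n_codons)))
        point = s + 3 * at_codon
        ins_len = int(rng.integers(54, 121))  # comfortably above the 50-nt rule
        insert = "GT" + _random_nt(rng, ins_len - 4) + "AG"
        contigs[parent] = seq[:point] + insert + seq[point:]
        manifest.at[idx, "anomaly"] = "intron_retained"
        manifest.at[idx, "parent_sequence"] = seq

    # frameshift: delete one base mid-ORF
    for idx in take(quotas.get("frameshifted", 0)):
        parent = manifest.at[idx, "contig_id"]
        seq = contigs[parent]
        s, e = int(manifest.at[idx, "orf_start"]), int(manifest.at[idx, "orf_end"])
        n_codons = (e - s) // 3
        if n_codons < 70:
            continue
        at = s + 3 * int(rng.integers(int(0.4 * n_codons), int(0.6 * n_codons)))
        contigs[parent] = seq[:at] + seq[at + 1 :]
        manifest.at[idx, "anomaly"] = "frameshifted"
        manifest.at[idx, "parent_sequence"] = seq

    for cid in drop:
        del contigs[cid]
    keep = ~manifest["contig_id"].isin(drop)
    contigs.update(new_contigs)
    if new_rows:
        return pd.concat([manifest[keep], pd.DataFrame(new_rows)], ignore_index=True)
    return manifest[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# profiles + counts
# ---------------------------------------------------------------------------

def assign_profiles(
    manifest: pd.DataFrame, design: SimDesign, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign archetypes and per-time-point mean FPKM to every contig.

    A ``de_fraction`` share of contigs receives one of the six archetypes
    (anomaly copies inherit their parent's profile); the rest are null
    (flat).  Baseline abundance is log-uniform over the configured range.
    """
    man = manifest.copy()
    lo, hi = design.baseline_fpkm_range
    arche_ids = sorted(design.archetypes)

    parents: dict[str, tuple[int, float]] = {}
    archetypes = np.zeros(len(man), dtype=int)
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(man)))
    is_de = rng.random(len(man)) < design.de_fraction
    choice = rng.integers(0, len(arche_ids), size=len(man))

    for i, row in enumerate(man.itertuples(index=False)):
        anomaly = row.anomaly
        parent = None
        if anomaly.startswith("redundant_of:"):
            parent = anomaly.split(":", 1)[1]
        elif anomaly.startswith("fragment_pair:"):
            parent = row.contig_id.rsplit("_frag", 1)[0]
        if parent is not None and parent in parents:
            archetypes[i], baselines[i] = parents[parent]
            continue
        if is_de[i]:
            archetypes[i] = arche_ids[choice[i]]
        key = (
            row.contig_id.rsplit("_frag", 1)[0]
            if "_frag" in row.contig_id
            else row.contig_id
        )
        parents[key] = (archetypes[i], baselines[i])

    man["archetype"] = archetypes
    for j, tp in enumerate(design.timepoints):
        offs = np.array(
            [design.archetypes[a][j] if a else 0.0 for a in archetypes]
        )
        man[f"mean_fpkm_{tp}"] = baselines * np.power(2.0, offs)
    man["dispersion"] = design.dispersion
    return man


def simulate_counts(
    manifest: pd.DataFrame,
    design: SimDesign,
    lengths: pd.Series,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB counts for every contig x sample; returns (counts, sample sheet).

    The mean for contig c in sample s is
    ``mean_fpkm[c, timepoint(s)] * length_c/1e3 * library_size_s/1e6``
    (the FPKM identity inverted); the NB has var = mu + phi*mu^2, drawn
    gamma-Poisson so phi=0 degenerates to Poisson exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    sheet = design.sample_sheet()
    lo, hi = design.library_size_range
    libs = rng.uniform(lo, hi, size=len(sheet))
    # the drawn depth is the *whole-transcriptome* library size; it is
    # recorded in the sheet because the contig subset's column sums do not
    # represent it
    sheet = sheet.assign(library_size=libs)
    phi = design.dispersion

    ids = manifest["contig_id"].to_numpy()
    lens = lengths.reindex(ids).to_numpy(dtype=float)
    mat = np.zeros((len(ids), len(sheet)), dtype=np.int64)
    for j, row in enumerate(sheet.itertuples(index=False)):
        means = (
            manifest[f"mean_fpkm_{row.timepoint_hps}"].to_numpy()
            * (lens / 1e3)
            * (libs[j] / 1e6)
        )
        if (means < 0).any():
            raise ValueError("negative planted means")
        if phi > 0:
            lam = rng.gamma(shape=1.0 / phi, scale=means * phi)
        else:
            lam = means
        mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=pd.Index(ids, name="contig_id"), columns=sheet["sample_id"])
    return counts, sheet


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(design: SimDesign) -> tuple[SyntheticDataset, pd.DataFrame]:
    """Run the full generator; returns (dataset, counts).

    The reference proteome holds the 'annotated' proteins; each comparator
    proteome is a diverged copy of reference + lineage proteins, so
    lineage-derived ORFs are conserved among comparators but absent from
    the reference — the planted 'conserved_uncharacterised' class.
    """
    rng = np.random.default_rng(design.seed)
    n_prot = max(40, design.n_contigs // 4)
    ref = simulate_proteome(n_prot, design.protein_length_range, rng, prefix="ref")
    lineage = simulate_proteome(n_prot // 2, design.protein_length_range, rng, prefix="lin")

    comparators = {}
    for c in range(design.n_comparators):
        pool = {**ref, **lineage}
        comparators[f"sp{c + 1}"] = {
            f"{pid}_sp{c + 1}": seq
            for pid, seq in diverge_proteome(pool, design.comparator_divergence, rng).items()
        }

    contigs, manifest = simulate_transcripts(ref, lineage, design, rng)

    # decoy database + contaminant contigs (planted copies of decoys)
    decoys = {
        f"decoy{i:03d}": _random_nt(rng, int(rng.integers(300, 900))) for i in range(20)
    }
    decoy_ids = sorted(decoys)
    for idx in manifest.index[manifest["class_label"] == "contaminant"]:
        cid = manifest.at[idx, "contig_id"]
        contigs[cid] = decoys[decoy_ids[int(rng.integers(len(decoy_ids)))]]

    manifest = assign_profiles(manifest, design, rng)

    # prior assembly: a share of contigs seen in an earlier assembly of the
    # same organism (supports the strict no-ORF cross-check)
    prior = {}
    for idx, row in manifest.iterrows():
        if rng.random() < design.prior_assembly_fraction:
            prior[f"prior_{row['contig_id']}"] = contigs[row["contig_id"]]

    lengths = pd.Series({cid: len(s) for cid, s in contigs.items()})
    counts, sheet = simulate_counts(manifest, design, lengths, rng)
    ds = SyntheticDataset(
        contigs=contigs,
        ref_proteome=ref,
        comparator_proteomes=comparators,
        decoy_db=decoys,
        prior_assembly=prior,
        manifest=manifest,
        design=design,
        sheet=sheet,
    )
    _validate(ds)
    return ds, counts


def _validate(ds: SyntheticDataset) -> None:
    man = ds.manifest
    ids = set(ds.contigs)
    listed = list(man["contig_id"])
    if sorted(listed) != sorted(ids) or len(set(listed)) != len(listed):
        raise AssertionError("manifest does not list every contig exactly once")
    for row in man.itertuples(index=False):
        if row.orf_start >= 0:
            seq = ds.contigs[row.contig_id]
            span = row.orf_end - row.orf_start
            if not (0 <= row.orf_start < row.orf_end <= len(seq)) and row.anomaly == "none":
                raise AssertionError(f"ORF span out of bounds for {row.contig_id}")
            if span % 3 != 0 and row.anomaly in ("none", "redundant_of"):
                raise AssertionError(f"ORF span not codon-aligned for {row.contig_id}")
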