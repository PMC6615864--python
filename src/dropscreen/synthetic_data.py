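"""Synthetic pooled-screen, dose-response and binding data with known truth.

The screen generator emulates the design of a dropout screen in cultured
cells: a hairpin library with log-normal baseline abundance is taken through
an infection bottleneck, grown for a fixed number of population doublings
with periodic passage bottlenecks at a stated per-hairpin coverage, and
finally sequenced with negative-binomial (gamma-Poisson) noise.  Gene
knockdowns carry a per-doubling selection coefficient ``s`` scaled by a
per-hairpin knockdown efficacy ``e_h`` in [0, 1]: over ``d`` doublings a
hairpin's cell count grows as ``2^{d (1 + e_h * s)}`` against ``2^d`` for
neutral hairpins, so its expected log2 fold change in relative abundance is
``d * e_h * s`` (e.g. d=15, s=-0.2, e_h=1 gives -3).

Sensitiser genes feel ``s_lig`` only under the matching ligand arm;
essential genes feel ``s_ess`` in every growth arm (DMSO included); nothing
is selected before t0, which is sampled straight after the infection
bottleneck.  Replicates are independent trajectories from the bottleneck on.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .screen_model import CountMatrix, SampleSheet, ShRNALibrary
from . import pharm_models

GENE_CLASSES = (
    "neutral",
    "essential",
    "sensitiser_PDS",
    "sensitiser_PhenDC3",
    "sensitiser_both",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ScreenSimParams:
    """Knobs of the screen generator; defaults follow the emulated design.

    coverage is cells-per-hairpin maintained at every bottleneck (1000x);
    doublings_total=15 with a passage every 3 doublings; 3 replicates;
    sequencing at a mean of 300 reads per hairpin with gamma-Poisson
    overdispersion phi_seq.  Selection strengths: s_lig=-0.2 per doubling for
    sensitisers under their ligand (expected log2FC -3 at full efficacy) and
    s_ess=-0.15 for essentials in all arms.  Knockdown efficacy e_h ~
    Beta(5, 2) (mean ~0.71); baseline abundance ~ LogNormal(0, 1).
    """

    n_genes: int = 1000
    hairpins_per_gene: int = 5
    frac_sensitiser_pds: float = 0.04
    frac_sensitiser_phendc3: float = 0.04
    frac_shared: float = 0.02
    frac_essential: float = 0.05
    s_lig: float = -0.2
    s_ess: float = -0.15
    efficacy_beta: tuple[float, float] = (5.0, 2.0)
    sigma_lib: float = 1.0
    coverage: int = 1000
    doublings_total: int = 15
    doublings_per_passage: int = 3
    seq_depth_per_hairpin: float = 300.0
    phi_seq: float = 0.05
    n_replicates: int = 3
    guide_length: int = 22
    pool: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_sensitiser_pds,
            self.frac_sensitiser_phendc3,
            self.frac_shared,
            self.frac_essential,
        )
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValidationError("gene-class fractions must be in [0,1] and sum <= 1")
        if self.coverage <= 0 or self.doublings_total <= 0:
            raise ValidationError("coverage and doublings_total must be positive")
        if self.n_genes * self.hairpins_per_gene > 4 ** self.guide_length:
            raise ValidationError("more hairpins requested than distinct guides exist")


@dataclass
class TruthTable:
    """Planted ground truth: per-gene class and per-hairpin efficacy/expected effect."""

    genes: pd.DataFrame      # gene, class
    hairpins: pd.DataFrame   # hairpin_id, gene, efficacy, expected_log2fc_{PDS,PhenDC3,DMSO}

    def genes_of_class(self, cls: str) -> set[str]:
        return set(self.genes.loc[self.genes["class"] == cls, "gene"])

    def sensitisers(self, ligand: str) -> set[str]:
        """Genes planted as sensitisers for a ligand (includes shared)."""
        return self.genes_of_class(f"sensitiser_{ligand}") | self.genes_of_class(
            "sensitiser_both"
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="list"),
            "hairpins": self.hairpins.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["genes"]), pd.DataFrame(payload["hairpins"]))


# ---------------------------------------------------------------------------
# library + truth
# ---------------------------------------------------------------------------


def _random_guides(n: int, length: int, rng: np.random.Generator) -> list[str]:
    seen: set[bytes] = set()
    guides: list[str] = []
    while len(guides) < n:
        block = rng.integers(0, 4, size=(n - len(guides), length))
        for row in _BASES[block]:
            key = row.tobytes()
            if key not in seen:
                seen.add(key)
                guides.append(key.decode())
    return guides


def make_library(params: ScreenSimParams) -> tuple[ShRNALibrary, TruthTable]:
    """Build a random library and its planted truth from the seeded RNG."""
    rng = np.random.default_rng(params.seed)
    G, hpg = params.n_genes, params.hairpins_per_gene
    H = G * hpg
    genes = [f"GENE{i:05d}" for i in range(G)]

    counts = {
        "sensitiser_PDS": round(params.frac_sensitiser_pds * G),
        "sensitiser_PhenDC3": round(params.frac_sensitiser_phendc3 * G),
        "sensitiser_both": round(params.frac_shared * G),
        "essential": round(params.frac_essential * G),
    }
    classes = np.array(["neutral"] * G, dtype=object)
    order = rng.permutation(G)
    pos = 0
    for cls, k in counts.items():
        classes[order[pos : pos + k]] = cls
        pos += k

    hairpin_ids = [f"sh{i:06d}" for i in range(H)]
    gene_per_hairpin = np.repeat(genes, hpg)
    lib = ShRNALibrary(
        pd.DataFrame(
            {
                "hairpin_id": hairpin_ids,
                "guide_seq": _random_guides(H, params.guide_length, rng),
                "gene": gene_per_hairpin,
                "pool": params.pool,
                "class": "target",
            }
        ),
        guide_length=params.guide_length,
    )

    a, b = params.efficacy_beta
    efficacy = rng.beta(a, b, size=H)
    cls_per_hairpin = np.repeat(classes, hpg)
    d = params.doublings_total
    s_for = {
        "PDS": np.where(
            np.isin(cls_per_hairpin, ["sensitiser_PDS", "sensitiser_both"]),
            params.s_lig,
            np.where(cls_per_hairpin == "essential", params.s_ess, 0.0),
        ),
        "PhenDC3": np.where(
            np.isin(cls_per_hairpin, ["sensitiser_PhenDC3", "sensitiser_both"]),
            params.s_lig,
            np.where(cls_per_hairpin == "essential", params.s_ess, 0.0),
        ),
        "DMSO": np.where(cls_per_hairpin == "essential", params.s_ess, 0.0),
    }
    truth = TruthTable(
        genes=pd.DataFrame({"gene": genes, "class": classes}),
        hairpins=pd.DataFrame(
            {
                "hairpin_id": hairpin_ids,
                "gene": gene_per_hairpin,
                "efficacy": efficacy,
                **{
                    f"expected_log2fc_{c}": d * efficacy * s
                    for c, s in s_for.items()
                },
            }
        ),
    )
    return lib, truth


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


def _nb_counts(mean: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mean`` and dispersion ``phi``."""
    mean = np.asarray(mean, dtype=float)
    if phi <= 0:
        return rng.poisson(mean)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(shape=1.0 / phi, scale=phi * mean[pos])
    return rng.poisson(lam)


def simulate_screen(
    lib: ShRNALibrary, truth: TruthTable, params: ScreenSimParams
) -> tuple[CountMatrix, SampleSheet]:
    """Run the bottleneck/growth/sequencing model for all arms and replicates.

    Per replicate: multinomial infection bottleneck to ``coverage * H``
    cells; t0 is sequenced from those cells; each arm (DMSO, PDS, PhenDC3)
    then grows in blocks of ``doublings_per_passage`` doublings -- cell
    counts scale by ``2^{dd (1 + e_h s)}`` -- with a multinomial passage
    bottleneck between blocks, and is sequenced after ``doublings_total``
    doublings.  Growth rates with ``1 + e_h s <= 0`` are clamped to zero
    cells.  Sequencing is gamma-Poisson around ``depth * H * q_h``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    th = truth.hairpins.set_index("hairpin_id").loc[lib.hairpin_ids]
    eff = th["efficacy"].to_numpy()
    H = lib.n_hairpins
    C = params.coverage * H
    d_total, d_pass = params.doublings_total, params.doublings_per_passage
    total_depth = params.seq_depth_per_hairpin * H

    # per-arm per-doubling growth exponents, clamped so 1 + e*s >= 0
    arms = ["DMSO", "PDS", "PhenDC3"]
    rate = {
        arm: np.maximum(th[f"expected_log2fc_{arm}"].to_numpy() / d_total + 1.0, 0.0)
        for arm in arms
    }

    baseline = rng.lognormal(mean=0.0, sigma=params.sigma_lib, size=H)
    baseline /= baseline.sum()

    # passage schedule: blocks of d_pass doublings, remainder in the last block
    blocks = [d_pass] * (d_total // d_pass)
    if d_total % d_pass:
        blocks.append(d_total % d_pass)

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for rep in range(1, params.n_replicates + 1):
        t0_cells = rng.multinomial(C, baseline).astype(float)
        sid = f"{params.pool}_t0_r{rep}"
        columns[sid] = _nb_counts(total_depth * t0_cells / C, params.phi_seq, rng)
        sheet_rows.append((sid, params.pool, "t0", "none", rep))
        for arm in arms:
            cells = t0_cells
            for i, dd in enumerate(blocks):
                grown = cells * np.exp2(dd * rate[arm])
                if i < len(blocks) - 1:
                    total = grown.sum()
                    if total <= 0:
                        raise ValidationError("population went extinct during growth")
                    cells = rng.multinomial(C, grown / total).astype(float)
                else:
                    cells = grown
            q = cells / cells.sum()
            sid = f"{params.pool}_{arm}_tF_r{rep}"
            columns[sid] = _nb_counts(total_depth * q, params.phi_seq, rng)
            sheet_rows.append((sid, params.pool, "tF", arm, rep))

    cm = CountMatrix(pd.DataFrame(columns, index=pd.Index(lib.hairpin_ids, name="hairpin_id")))
    ss = SampleSheet(
        pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "pool", "timepoint", "treatment", "replicate"],
        )
    )
    return cm, ss


# ---------------------------------------------------------------------------
# FASTQ simulation
# ---------------------------------------------------------------------------


def simulate_fastq(
    cm: CountMatrix,
    lib: ShRNALibrary,
    outdir: str | Path,
    error_rate: float = 0.0,
    read_len: int = 36,
    seed: int = 0,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write one FASTQ per sample: one read per count, guide at the read start.

    Reads are padded to ``read_len`` with random bases and hit with iid
    substitutions at ``error_rate``; qualities are constant Q40 (Phred+33
    'I').  With ``error_rate=0`` the quantifier reproduces ``cm`` exactly.
    """
    if read_len < lib.guide_length:
        raise ValidationError("read_len must be >= guide length")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    guide_u8 = np.frombuffer(
        "".join(lib.table["guide_seq"]).encode(), dtype=np.uint8
    ).reshape(lib.n_hairpins, lib.guide_length)
    paths: dict[str, Path] = {}
    base_to_idx = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_to_idx[b] = i
    for sample in cm.sample_ids:
        counts = cm.counts[sample].to_numpy()
        n_reads = int(counts.sum())
        idx = rng.permutation(np.repeat(np.arange(lib.n_hairpins), counts))
        reads = guide_u8[idx]
        pad = read_len - lib.guide_length
        if pad:
            tail = _BASES[rng.integers(0, 4, size=(n_reads, pad))]
            reads = np.concatenate([reads, tail], axis=1) if n_reads else np.empty(
                (0, read_len), dtype=np.uint8
            )
        if error_rate > 0 and n_reads:
            mask = rng.random(reads.shape) < error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()))
            cur = base_to_idx[reads[mask]]
            reads[mask] = _BASES[(cur + shift) % 4]
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = outdir / f"{sample}{suffix}"
        opener = gzip.open if gzip_output else open
        qual = "I" * read_len
        with opener(path, "wt") as fh:
            for i in range(n_reads):
                fh.write(
                    f"@{sample}:{i}\n{reads[i].tobytes().decode()}\n+\n{qual}\n"
                )
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# pharmacology simulators
# ---------------------------------------------------------------------------


def simulate_dose_response(
    top: float,
    bottom: float,
    log_ic50: float,
    hill: float,
    doses: Sequence[float],
    sigma_noise: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Four-parameter logistic responses plus Gaussian noise.

    Returns a long table with columns ``dose, replicate, response``.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValidationError("doses must be positive")
    rng = np.random.default_rng(seed)
    clean = pharm_models.four_pl(doses, top, bottom, log_ic50, hill)
    rows = []
    for rep in range(1, n_replicates + 1):
        noise = rng.normal(0.0, sigma_noise, size=doses.size) if sigma_noise > 0 else 0.0
        rows.append(
            pd.DataFrame({"dose": doses, "replicate": rep, "response": clean + noise})
        )
    return pd.concat(rows, ignore_index=True)


def simulate_binding_curve(
    bmax: float,
    kd: float,
    concentrations: Sequence[float],
    sigma_noise: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One-site specific binding ``y = Bmax x / (Kd + x)`` plus Gaussian noise."""
    x = np.asarray(concentrations, dtype=float)
    if np.any(x < 0):
        raise ValidationError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    y = bmax * x / (kd + x)
    if sigma_noise > 0:
        y = y + rng.normal(0.0, sigma_noise, size=x.size)
    return pd.DataFrame({"concentration": x, "signal": y})
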