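"""Synthetic diploid smRNA-FISH dataset generator.

The generator emulates the *output* of a spot-detection pipeline (one row per
detected fluorescent spot), not images.  Per cell:

* an extrinsic activity factor ``a_c ~ LogNormal(0, extrinsic_sigma)``
  multiplies burst probabilities and telegraph frequency, modelling global
  cell-to-cell variability that correlates loci without allele-level coupling;
* each allele draws a bivariate Bernoulli pair (enhancer state, gene state)
  with marginals ``clip(p * a_c, 0, 1)`` and coupling odds ratio ``psi``;
* an active TSS carries ``1 + Poisson(lambda_nascent)`` nascent transcripts
  and appears as a nuclear spot of intensity ``k * I1 * (1 + eps)``;
* mature mRNA per allele is Gamma-Poisson (telegraph bursty limit) and is
  rendered as cytoplasmic single-molecule spots;
* alleles sit uniformly in the nuclear sphere subject to a minimum
  separation, the enhancer locus is offset from the gene locus by a short
  cis displacement, and every spot position receives isotropic localization
  error plus a per-channel chromatic shift.

Everything is drawn from one `numpy` generator seeded from the config, so a
(config, seed) pair reproduces the dataset exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from burstlink.errors import ConfigError
from burstlink.io import Dataset
from burstlink.params import SimulationConfig

__all__ = ["joint_burst_probability", "simulate_dataset"]


def joint_burst_probability(p_e, p_g, psi):
    """Joint probability that enhancer and gene are both active.

    Solves the odds-ratio identity ``psi = p11*p00 / (p10*p01)`` for the
    joint probability ``p11`` given the marginals, i.e. the admissible root
    of ``(psi-1)*p11**2 - [(psi-1)*(p_e+p_g) + 1]*p11 + psi*p_e*p_g = 0``
    (the Plackett construction for a 2x2 table).  ``psi = 1`` returns the
    independence product; ``psi = inf`` the Frechet upper bound
    ``min(p_e, p_g)``; ``psi = 0`` the lower bound ``max(0, p_e+p_g-1)``.

    Accepts scalars or broadcastable arrays.
    """
    p_e = np.asarray(p_e, dtype=float)
    p_g = np.asarray(p_g, dtype=float)
    psi_arr = np.asarray(psi, dtype=float)
    if np.any(psi_arr < 0):
        raise ValueError("psi must be >= 0")
    if np.any((p_e < 0) | (p_e > 1) | (p_g < 0) | (p_g > 1)):
        raise ValueError("marginal probabilities must lie in [0, 1]")

    p_e, p_g, psi_arr = np.broadcast_arrays(p_e, p_g, psi_arr)
    lower = np.maximum(0.0, p_e + p_g - 1.0)
    upper = np.minimum(p_e, p_g)

    with np.errstate(invalid="ignore", divide="ignore"):
        # stable closed form of the admissible quadratic root
        s = 1.0 + (psi_arr - 1.0) * (p_e + p_g)
        disc = s * s - 4.0 * psi_arr * (psi_arr - 1.0) * p_e * p_g
        root = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * (psi_arr - 1.0))

    p11 = np.where(psi_arr == 1.0, p_e * p_g, root)
    p11 = np.where(np.isinf(psi_arr), upper, p11)
    p11 = np.where(psi_arr == 0.0, lower, p11)
    # degenerate marginals: boundary value without solving
    p11 = np.where((p_e == 0.0) | (p_g == 0.0), 0.0, p11)
    p11 = np.where(p_e == 1.0, p_g, p11)
    p11 = np.where(p_g == 1.0, np.where(p_e == 1.0, 1.0, p_e), p11)
    p11 = np.clip(p11, lower, upper)
    if p11.ndim == 0:
        return float(p11)
    return p11


def _uniform_in_sphere(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return v * r[:, None]


def _uniform_in_shell(
    rng: np.random.Generator, n: int, r_inner: float, r_outer: float
) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random(n)
    r = (r_inner**3 + u * (r_outer**3 - r_inner**3)) ** (1.0 / 3.0)
    return v * r[:, None]


def _allele_positions(
    rng: np.random.Generator, n_cells: int, ploidy: int, radius: float, min_sep: float
) -> np.ndarray:
    """(n_cells, ploidy, 3) positions, pairwise separation >= min_sep."""
    pos = _uniform_in_sphere(rng, n_cells * ploidy, radius).reshape(n_cells, ploidy, 3)
    if ploidy < 2:
        return pos
    for _ in range(1000):
        diff = pos[:, :, None, :] - pos[:, None, :, :]
        d = np.sqrt((diff**2).sum(-1))
        iu = np.triu_indices(ploidy, k=1)
        bad = (d[:, iu[0], iu[1]] < min_sep).any(axis=1)
        if not bad.any():
            return pos
        n_bad = int(bad.sum())
        pos[bad] = _uniform_in_sphere(rng, n_bad * ploidy, radius).reshape(n_bad, ploidy, 3)
    raise ConfigError(
        "could not place alleles with the requested minimum separation; "
        "min_allele_separation is too close to the nucleus diameter"
    )


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> Dataset:
    """Simulate a spot-level dataset with ground truth.

    Returns a :class:`~burstlink.io.Dataset` with ``cells``, ``spots`` and
    ``truth`` tables.  ``seed`` overrides ``config.seed`` when given.
    """
    config.validate()
    geom = config.geometry
    if geom.min_allele_separation >= 2 * geom.nucleus_radius:
        raise ConfigError("min_allele_separation must be < 2 * nucleus_radius")

    rng = np.random.default_rng(config.seed if seed is None else int(seed))

    n_cond = len(config.conditions)
    n_rep = config.n_replicates
    n_per = config.n_cells_per_replicate
    ploidy = config.ploidy
    n = n_cond * n_rep * n_per

    cond_idx = np.repeat(np.arange(n_cond), n_rep * n_per)
    rep_idx = np.tile(np.repeat(np.arange(1, n_rep + 1), n_per), n_cond)
    cell_id = np.arange(n, dtype=np.int64)

    kin = [c.kinetics for c in config.conditions]

    def karr(attr: str) -> np.ndarray:
        return np.asarray([getattr(k, attr) for k in kin], dtype=float)[cond_idx]

    p_e, p_g, psi = karr("p_e"), karr("p_g"), karr("psi")
    f, b, lam = karr("f"), karr("b"), karr("lambda_nascent")
    detect_prob, false_rate = karr("detect_prob"), karr("false_tss_rate")

    sig = config.noise.extrinsic_sigma
    a_c = rng.lognormal(0.0, sig, n) if sig > 0 else np.ones(n)

    # allele burst states: bivariate Bernoulli with odds ratio psi
    pe_eff = np.clip(p_e * a_c, 0.0, 1.0)[:, None]
    pg_eff = np.clip(p_g * a_c, 0.0, 1.0)[:, None]
    p11 = joint_burst_probability(
        np.broadcast_to(pe_eff, (n, ploidy)),
        np.broadcast_to(pg_eff, (n, ploidy)),
        psi[:, None],
    )
    p11 = np.asarray(p11)
    p01 = pg_eff - p11  # gene only
    u = rng.random((n, ploidy))
    enh_state = u < pe_eff  # {11, 10} region
    gene_state = (u < p11) | ((u >= pe_eff) & (u < pe_eff + p01))

    k_enh = np.where(enh_state, 1 + rng.poisson(lam[:, None], (n, ploidy)), 0)
    k_gene = np.where(gene_state, 1 + rng.poisson(lam[:, None], (n, ploidy)), 0)

    # mature mRNA: Gamma-Poisson (negative binomial) bursty steady state
    shape = np.broadcast_to((f * a_c)[:, None], (n, ploidy))
    mature = rng.poisson(rng.gamma(shape, b[:, None]))

    # geometry -----------------------------------------------------------
    r_nuc = geom.nucleus_radius
    grid = int(np.ceil(np.sqrt(n)))
    centers = np.column_stack(
        [
            30.0 * (cell_id % grid),
            30.0 * (cell_id // grid),
            np.zeros(n),
        ]
    )
    gene_pos = _allele_positions(rng, n, ploidy, r_nuc, geom.min_allele_separation)
    cis_r = np.clip(
        rng.normal(geom.cis_separation_mean, geom.cis_separation_sd, (n, ploidy)), 0.0, None
    )
    cis_dir = rng.normal(size=(n, ploidy, 3))
    cis_dir /= np.linalg.norm(cis_dir, axis=2, keepdims=True)
    enh_pos = gene_pos + cis_r[..., None] * cis_dir
    gene_abs = gene_pos + centers[:, None, :]
    enh_abs = enh_pos + centers[:, None, :]

    # spot assembly ------------------------------------------------------
    i1 = config.single_molecule_intensity
    cv = config.noise.intensity_cv
    loc = geom.localization_sigma
    blocks: list[pd.DataFrame] = []

    def intensity(k: np.ndarray) -> np.ndarray:
        return np.maximum(k * i1 * (1.0 + rng.normal(0.0, cv, k.shape)), 1e-3)

    def spot_block(pos, inten, cells, probe, channel, compartment) -> pd.DataFrame:
        shift = geom.chromatic_shift.get(channel, (0.0, 0.0))
        noisy = pos + rng.normal(0.0, loc, pos.shape)
        return pd.DataFrame(
            {
                "cell_id": cells,
                "probe_id": probe,
                "channel": channel,
                "x": noisy[:, 0] + shift[0],
                "y": noisy[:, 1] + shift[1],
                "z": noisy[:, 2],
                "intensity": inten,
                "compartment": compartment,
            }
        )

    for probe in config.probes:
        if probe.role == "enhancer":
            state, k_tss, base = enh_state, k_enh, enh_abs
        else:
            state, k_tss, base = gene_state, k_gene, gene_abs

        detected = state & (rng.random((n, ploidy)) < detect_prob[:, None])
        ci, ai = np.nonzero(detected)
        if ci.size:
            blocks.append(
                spot_block(
                    base[ci, ai],
                    intensity(k_tss[ci, ai]),
                    cell_id[ci],
                    probe.probe_id,
                    probe.channel,
                    "nuclear",
                )
            )

        # single-molecule spots anchoring the reference intensity
        if probe.role == "gene_exon":
            counts = mature.sum(axis=1)
        else:
            counts = rng.poisson(config.singles_mean, n)
        tot = int(counts.sum())
        if tot:
            cells_rep = np.repeat(cell_id, counts)
            pos = _uniform_in_shell(rng, tot, r_nuc, 1.5 * r_nuc) + centers[cells_rep]
            blocks.append(
                spot_block(
                    pos,
                    intensity(np.ones(tot)),
                    cells_rep,
                    probe.probe_id,
                    probe.channel,
                    "cytoplasmic",
                )
            )

        # spurious bright nuclear spots (rate shared across channels)
        n_false = rng.poisson(false_rate / len(config.probes), n)
        tot = int(n_false.sum())
        if tot:
            cells_rep = np.repeat(cell_id, n_false)
            pos = _uniform_in_sphere(rng, tot, r_nuc) + centers[cells_rep]
            blocks.append(
                spot_block(
                    pos,
                    intensity(1 + rng.poisson(lam[cells_rep])),
                    cells_rep,
                    probe.probe_id,
                    probe.channel,
                    "nuclear",
                )
            )

    spots = (
        pd.concat(blocks, ignore_index=True)
        if blocks
        else pd.DataFrame(
            columns=["cell_id", "probe_id", "channel", "x", "y", "z", "intensity", "compartment"]
        )
    )
    spots.insert(0, "spot_id", np.arange(len(spots), dtype=np.int64))

    cond_labels = np.asarray([c.label for c in config.conditions], dtype=object)
    cells = pd.DataFrame(
        {
            "cell_id": cell_id,
            "replicate_id": rep_idx,
            "condition": cond_labels[cond_idx],
            "nx": centers[:, 0],
            "ny": centers[:, 1],
            "nz": centers[:, 2],
            "nucleus_radius": r_nuc,
        }
    )

    allele = np.tile(np.arange(ploidy), n)
    rows = np.repeat(cell_id, ploidy)
    truth = pd.DataFrame(
        {
            "cell_id": rows,
            "allele": allele,
            "enhancer_state": enh_state.reshape(-1).astype(np.int64),
            "gene_state": gene_state.reshape(-1).astype(np.int64),
            "nascent_count": k_gene.reshape(-1).astype(np.int64),
            "enhancer_nascent": k_enh.reshape(-1).astype(np.int64),
            "mature_count": mature.reshape(-1).astype(np.int64),
            "gene_x": gene_abs[:, :, 0].reshape(-1),
            "gene_y": gene_abs[:, :, 1].reshape(-1),
            "gene_z": gene_abs[:, :, 2].reshape(-1),
            "enh_x": enh_abs[:, :, 0].reshape(-1),
            "enh_y": enh_abs[:, :, 1].reshape(-1),
            "enh_z": enh_abs[:, :, 2].reshape(-1),
            "extrinsic_factor": np.repeat(a_c, ploidy),
        }
    )

    return Dataset(cells=cells, spots=spots, truth=truth)
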