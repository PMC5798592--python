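"""Pictographic reading: a deep mixed (discrete + continuous) simulation.

The synthetic world contains six sentences of four words each, drawn from a
three-word lexicon ``{flee, feed, wait}``.  Each word is displayed as a pair
of pictograms in the quadrants of the visual field: *flee* places a bird
next to a cat, *feed* a bird next to seeds, and *wait* puts seeds above (or
below) a bird.  Two binary hidden states flip the arrangement vertically
(font substitution) and horizontally (letter order), and empty quadrants
show nothing — observing emptiness is itself evidence.

The generative model has two discrete levels and one continuous level:

* level 2 — hidden states: sentence (6) x word position (4); outcomes: the
  word implied by the sentence at the current position (linking down) and a
  proprioceptive position signal;
* level 1 — hidden states: word (3) x fixated quadrant (4) x vertical flip
  (2) x horizontal flip (2); outcomes: the pictogram seen (*what*) and the
  fixation location (*where*); the quadrant is controllable, and saccades
  are chosen by expected free energy with neutral preferences, i.e. purely
  epistemically;
* continuous — hidden causes: a 2-D target location and a 4-vector of
  pictogram weights; a single hidden state, the 2-D center of gaze, which
  is attracted to the target while action moves the eye.  Visual input is
  the pictogram image, shifted by the displacement between target and gaze
  and contrast-attenuated by a Gaussian function of that displacement
  (sensory attenuation), alongside proprioceptive gaze.

The levels communicate through initial-state links (descending empirical
priors and ascending evidence) and, at the bottom, through the Gaussian
link node: each (pictogram, quadrant) pair is an outcome model with a
Gaussian prior over the continuous causes, scored by accumulated reduced
log evidence during each saccade.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage, signal

from ._util import LOG_FLOOR, entropy, log_stable, normalize, onehot, softmax
from .continuous_engine import (ContinuousModel, ContinuousProcess,
                                GeneralizedState)
from .discrete_engine import (ascending_message, bayesian_model_average,
                              descending_message, expected_free_energy,
                              expected_outcomes, gradient_iteration,
                              _log_priors, _obs_logpots,
                              marginal_free_energy, policy_posterior,
                              select_action)
from .discrete_model import DiscreteModel, validate_model
from .link_node import LinkSpec, link_cycle

WORDS = ("flee", "feed", "wait")
GLYPH_NAMES = ("bird", "cat", "seeds", "blank")
BIRD, CAT, SEEDS, BLANK = range(4)

#: quadrant centers in gaze units; the field of view is [-1, 1]^2 and the
#: quadrant order is upper-left, upper-right, lower-left, lower-right
QUADRANT_CENTERS = np.array([[-0.5, 0.5], [0.5, 0.5],
                             [-0.5, -0.5], [0.5, -0.5]])

#: canonical un-flipped layouts, quadrant -> glyph
_BASE_LAYOUT = {
    "flee": (BIRD, CAT, BLANK, BLANK),    # bird next to a cat
    "feed": (BIRD, SEEDS, BLANK, BLANK),  # bird next to some seeds
    "wait": (SEEDS, BLANK, BIRD, BLANK),  # seeds above the bird
}

#: the six sentences as word indices into WORDS.  Sentences 0 and 3 share
#: their first three words, so the final word disambiguates them — the
#: exact sentence set is a reconstruction, chosen to reproduce that
#: narrative structure, and is configurable.
DEFAULT_SENTENCES = (
    (0, 1, 2, 1),   # flee feed wait feed
    (1, 2, 0, 2),   # feed wait flee wait
    (2, 0, 1, 0),   # wait flee feed flee
    (0, 1, 2, 0),   # flee feed wait flee
    (2, 1, 1, 2),   # wait feed feed wait
    (1, 0, 2, 1),   # feed flee wait feed
)


@dataclass
class ReadingConfig:
    """Every default of the simulation, overridable from a config file."""

    sentences: tuple = DEFAULT_SENTENCES
    true_sentence: int = 0
    true_flips: tuple = (0, 0)
    glyph_seed: int = 7
    attenuation_sigma: float = 0.5       # gaze units
    pixels_per_unit: float = 16.0
    glyph_energy: float = 150.0          # common squared-norm of pictograms
    kappa: float = 8.0                   # attractor rate of the gaze flow
    n_steps_per_saccade: int = 24        # ~256 ms at ~10.7 ms per step
    dt: float = 1.0 / 24.0
    pi_vis: float = 1.0                  # visual outcome precision per pixel
    pi_prop: float = 8.0                 # proprioceptive precision (order 0)
    pi_prop_vel: float = 0.5             # proprioceptive precision (order 1)
    pi_flow: float = 8.0                 # state-noise precision (variance 1/8)
    pi_flow_top: float = 0.5             # top embedding order
    pi_loc_prior: float = 16.0           # link prior precision, location
    pi_id_prior: float = 4.0             # link prior precision, identity
    action_gain: float = 32.0            # oculomotor sensitivity do/da
    process_noise_var: float = 1.0 / 8.0
    obs_noise_var: float = 1.0 / 8.0
    flip_prior: float = 0.75             # prior mass on the canonical
                                         # (unflipped) orientation per axis
    iterations: int = 16                 # gradient iterations per epoch
    step: float = 0.25
    gamma: float = 1.0
    T1: int = 3                          # level-1 epochs per word
    bin_dt: float = 0.016                # ephys: seconds per iteration bin
    band: tuple = (4.0, 32.0)            # ephys band-pass, Hz

    @classmethod
    def from_dict(cls, d: dict) -> "ReadingConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        d = dict(d)
        for key in ("sentences", "true_flips", "band"):
            if key in d:
                d[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                               for x in d[key]) if key == "sentences" else tuple(d[key])
        return cls(**d)


@dataclass
class ReadingWorld:
    """The synthetic environment: sentence set, layouts, pictograms and
    geometry, plus the generating configuration (the process side)."""

    sentences: tuple
    word_layouts: dict            # (word, vflip, hflip) -> quadrant glyphs
    glyphs: np.ndarray            # (4, 32, 32) grayscale in [0, 1]
    quadrant_centers: np.ndarray
    attenuation_sigma: float
    pixels_per_unit: float
    true_sentence: int
    true_flips: tuple


def word_layout(word: int, vflip: int, hflip: int) -> tuple:
    """Quadrant-to-glyph mapping for one word under the two flips."""
    base = list(_BASE_LAYOUT[WORDS[word]])
    if vflip:  # swap rows
        base = [base[2], base[3], base[0], base[1]]
    if hflip:  # swap columns
        base = [base[1], base[0], base[3], base[2]]
    return tuple(base)


def make_glyphs(seed: int = 7, energy: float = 150.0) -> np.ndarray:
    """Deterministic 32x32 pictograms for bird / cat / seeds / blank.

    Shapes are procedural (the pictogram content only needs to be
    discriminable): an ellipse-bodied bird, a round-headed cat with ears,
    and a jittered grid of seeds.  Images are lightly blurred and rescaled
    to a common energy so that each pictogram supports a comparable amount
    of visual evidence; pairwise correlations stay below 0.5.
    """
    yy, xx = np.mgrid[0:32, 0:32]

    def disk(cx, cy, r):
        return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r * r).astype(float)

    bird = np.clip(
        ((((yy - 13) / 5.0) ** 2 + ((xx - 12) / 8.0) ** 2) <= 1).astype(float)
        + disk(22, 9, 3.5)
        + ((np.abs(xx - 12) + np.abs(yy - 22) <= 5) & (yy >= 17)).astype(float),
        0, 1)
    cat = np.clip(
        disk(20, 20, 7.5)
        + ((yy <= 14) & (yy >= 8) & (np.abs(xx - 15) <= (yy - 8) // 2 + 1)).astype(float)
        + ((yy <= 14) & (yy >= 8) & (np.abs(xx - 25) <= (yy - 8) // 2 + 1)).astype(float),
        0, 1)
    rng = np.random.default_rng(seed)
    seeds = np.zeros((32, 32))
    for gy in range(4, 32, 8):
        for gx in range(4, 32, 8):
            seeds += disk(gx + rng.integers(-1, 2), gy + rng.integers(-1, 2), 2.4)
    seeds = np.clip(seeds, 0, 1)

    out = np.zeros((4, 32, 32))
    for i, im in enumerate((bird, cat, seeds)):
        im = ndimage.gaussian_filter(im, 1.2)
        im = np.clip(im * np.sqrt(energy / (im ** 2).sum()), 0, 1)
        out[i] = im
    return out


def build_world(config: ReadingConfig) -> ReadingWorld:
    layouts = {(w, vf, hf): word_layout(w, vf, hf)
               for w in range(3) for vf in range(2) for hf in range(2)}
    return ReadingWorld(
        sentences=tuple(tuple(s) for s in config.sentences),
        word_layouts=layouts,
        glyphs=make_glyphs(config.glyph_seed, config.glyph_energy),
        quadrant_centers=QUADRANT_CENTERS.copy(),
        attenuation_sigma=config.attenuation_sigma,
        pixels_per_unit=config.pixels_per_unit,
        true_sentence=config.true_sentence,
        true_flips=tuple(config.true_flips),
    )


def sample_visual(world: ReadingWorld, glyph, gaze, target) -> np.ndarray:
    """Eccentric, attenuated visual sample of a pictogram.

    The glyph image (an index or a 32x32 array) sitting at ``target`` is
    shifted by the displacement ``d = target - gaze`` and multiplied by the
    contrast factor ``exp(-|d|^2 / (2 sigma^2))``; fixating the target
    yields the unattenuated glyph.
    """
    if np.isscalar(glyph):
        glyph = world.glyphs[int(glyph)]
    d = np.asarray(target, dtype=float) - np.asarray(gaze, dtype=float)
    att = float(np.exp(-(d @ d) / (2.0 * world.attenuation_sigma ** 2)))
    if att < LOG_FLOOR:
        return np.zeros_like(glyph)
    ppu = world.pixels_per_unit
    shifted = ndimage.shift(glyph, (-d[1] * ppu, d[0] * ppu), order=1, cval=0.0)
    return att * shifted


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _level1_model(world: ReadingWorld, config: ReadingConfig) -> DiscreteModel:
    # factors: word(3) x quadrant(4) x vflip(2) x hflip(2)
    A_what = np.zeros((4, 3, 4, 2, 2))
    A_where = np.zeros((4, 3, 4, 2, 2))
    for w in range(3):
        for q in range(4):
            for vf in range(2):
                for hf in range(2):
                    A_what[world.word_layouts[(w, vf, hf)][q], w, q, vf, hf] = 1.0
                    A_where[q, w, q, vf, hf] = 1.0
    B_word = np.eye(3)[:, :, None]
    B_quad = np.zeros((4, 4, 4))
    for a in range(4):
        B_quad[a, :, a] = 1.0          # a saccade lands where it was sent
    B_flip = np.eye(2)[:, :, None]
    # depth-2 policies over the controllable quadrant factor
    policies = np.array([[[p // 4], [p % 4]] for p in range(16)]).transpose(1, 0, 2)
    # the canonical orientation is a priori more probable; this breaks the
    # exact symmetry between quadrants so that epistemic saccades have a
    # well-defined (and informative) ordering
    d_flip = np.array([config.flip_prior, 1.0 - config.flip_prior])
    return DiscreteModel(
        A=[A_what, A_where],
        B=[B_word, B_quad, B_flip, B_flip.copy()],
        D=[np.full(3, 1 / 3), np.full(4, 1 / 4), d_flip, d_flip.copy()],
        policies=policies, T=config.T1, control_factors=(1,),
    )


def _level2_model(world: ReadingWorld) -> DiscreteModel:
    n_s = len(world.sentences)
    A_pos = np.zeros((4, n_s, 4))
    for s in range(n_s):
        for p in range(4):
            A_pos[p, s, p] = 1.0
    B_sent = np.eye(n_s)[:, :, None]
    B_pos = np.zeros((4, 4, 1))
    for p in range(4):
        B_pos[min(p + 1, 3), p, 0] = 1.0   # the narrative advances
    return DiscreteModel(
        A=[A_pos],
        B=[B_sent, B_pos],
        D=[np.full(n_s, 1 / n_s), onehot(0, 4)],
        T=4,
    )


def word_link_matrix(world: ReadingWorld) -> np.ndarray:
    """The matrix-valued initial-state prior linking levels: column
    ``(sentence, position)`` is the (here deterministic) distribution over
    the word the lower level starts in."""
    n_s = len(world.sentences)
    D = np.zeros((3, n_s * 4))
    for s in range(n_s):
        for p in range(4):
            D[world.sentences[s][p], s * 4 + p] = 1.0
    return D


def _link_models(world: ReadingWorld, config: ReadingConfig) -> list:
    """One Gaussian prior over the continuous causes per (glyph, quadrant)
    outcome model; index ``m = glyph * 4 + quadrant``."""
    Pi = np.diag([config.pi_loc_prior] * 2 + [config.pi_id_prior] * 4)
    return [(np.concatenate([world.quadrant_centers[q], onehot(g, 4)]), Pi)
            for g in range(4) for q in range(4)]


def _continuous_model(world: ReadingWorld, config: ReadingConfig) -> ContinuousModel:
    """Gaze model: 2-D gaze attracted to the location cause; outcomes are
    the 1024-pixel attenuated pictogram plus proprioceptive gaze.

    Jacobians are analytic and first order: visual gradients flow through
    the contrast attenuation (the sub-pixel image shift is treated as part
    of the residual), which keeps the filter well conditioned.
    """
    sig = world.attenuation_sigma
    kap = config.kappa
    ppu = world.pixels_per_unit

    def shifted(d):
        return [ndimage.shift(world.glyphs[k], (-d[1] * ppu, d[0] * ppu),
                              order=1, cval=0.0).ravel() for k in range(4)]

    def g(x, v):
        vL, vI = v[:2], v[2:]
        vis = sum(vI[k] * sample_visual(world, k, x, vL) for k in range(4))
        return np.concatenate([vis.ravel(), x])

    def gx(x, v):
        vL, vI = v[:2], v[2:]
        d = vL - x
        att = np.exp(-(d @ d) / (2 * sig ** 2))
        S = shifted(d)
        base = sum(vI[k] * S[k] for k in range(4))
        return np.vstack([np.outer(base, att * d / sig ** 2), np.eye(2)])

    def gv(x, v):
        vL, vI = v[:2], v[2:]
        d = vL - x
        att = np.exp(-(d @ d) / (2 * sig ** 2))
        S = shifted(d)
        base = sum(vI[k] * S[k] for k in range(4))
        J_loc = np.outer(base, -att * d / sig ** 2)
        J_id = att * np.stack(S, axis=1)
        return np.vstack([np.hstack([J_loc, J_id]), np.zeros((2, 6))])

    Pi0 = np.concatenate([np.full(1024, config.pi_vis), np.full(2, config.pi_prop)])
    Pi1 = np.concatenate([np.full(1024, 1e-8), np.full(2, config.pi_prop_vel)])
    return ContinuousModel(
        g=g, f=lambda x, v: kap * (v[:2] - x),
        dim_x=2, dim_v=6, dim_o=1026, n_orders=2,
        Pi_o=[np.diag(Pi0), np.diag(Pi1)],
        Pi_x=[config.pi_flow * np.eye(2), config.pi_flow_top * np.eye(2)],
        gx=gx, gv=gv,
        fx=lambda x, v: -kap * np.eye(2),
        fv=lambda x, v: np.hstack([kap * np.eye(2), np.zeros((2, 4))]),
    )


def build_reading_model(config: ReadingConfig | dict | None = None):
    """Assemble the full generative stack.

    Returns ``(level2, level1, link_models, continuous_model, world)``; all
    discrete pieces pass :func:`~actinf.discrete_model.validate_model`.
    """
    if config is None:
        config = ReadingConfig()
    elif isinstance(config, dict):
        config = ReadingConfig.from_dict(config)
    world = build_world(config)
    if len(world.sentences) != 6 or any(len(s) != 4 for s in world.sentences):
        raise ValueError("the reading world requires 6 sentences of 4 words")
    level2 = _level2_model(world)
    level1 = _level1_model(world, config)
    for name, m in (("level2", level2), ("level1", level1)):
        rep = validate_model(m)
        if not rep.ok:
            raise ValueError(f"{name} model invalid: {rep.problems}")
    link_models = _link_models(world, config)
    cont = _continuous_model(world, config)
    return level2, level1, link_models, cont, world


# ---------------------------------------------------------------------------
# the full simulation
# ---------------------------------------------------------------------------

@dataclass
class SaccadeRecord:
    word_index: int
    epoch: int
    target_quadrant: int
    true_glyph: int
    gaze: np.ndarray              # (n_steps, 2) true gaze path
    mu_gaze: np.ndarray           # believed gaze path
    action: np.ndarray
    posterior_o: np.ndarray       # (16,) link posterior over outcome models
    what_weights: np.ndarray      # (4,) accumulated-evidence weights
    F: np.ndarray


@dataclass
class EphysRecord:
    """Simulated electrophysiology: firing-rate rasters (Bayesian model
    averages per unit per iteration bin) and band-passed depolarization
    traces, with saccade onset times."""

    rasters: dict                 # name -> (units, bins) in [0, 1]
    lfp: dict                     # name -> (units, samples) filtered traces
    fs: float                     # sample rate of the lfp traces, Hz
    bin_dt: float
    band: tuple
    times: np.ndarray             # lfp sample times, s
    bin_times: np.ndarray
    saccade_onsets: np.ndarray    # s


@dataclass
class ReadingRecord:
    config: ReadingConfig = None
    world: ReadingWorld = None
    words_read: list = field(default_factory=list)       # level-1 records
    saccades: list = field(default_factory=list)
    sentence_bma: list = field(default_factory=list)     # after each word
    word_bma: list = field(default_factory=list)
    sentence_entropy: list = field(default_factory=list)
    level2_raster: np.ndarray = None
    level1_raster: np.ndarray = None
    saccade_onset_bins: list = field(default_factory=list)
    ephys: EphysRecord = None

    @property
    def inferred_sentence(self) -> int:
        return int(np.argmax(self.sentence_bma[-1]))


def _predict_what(level1, s_all, pi, tau, quadrant):
    """Predicted pictogram distribution at a future epoch, given the
    commanded quadrant and current (policy-averaged) beliefs."""
    bma = bayesian_model_average(s_all, pi)
    s_tau = [bma[0][tau], onehot(quadrant, 4), bma[2][tau], bma[3][tau]]
    return expected_outcomes(level1.A, s_tau)[0]


def run_reading(seed: int = 1, config: ReadingConfig | dict | None = None) -> ReadingRecord:
    """Execute the complete reading simulation.

    For each of the four words: the sentence level sends a descending
    empirical prior over the word; the word level plans saccades by
    expected free energy, and each selected saccade opens a continuous
    window in which gaze is enacted and the link node accumulates evidence
    over (pictogram, quadrant) outcome models; the resulting soft outcomes
    update the word level, whose posterior ascends to the sentence level.
    Strict alternation throughout: a level waits for the level below.
    """
    if config is None:
        config = ReadingConfig()
    elif isinstance(config, dict):
        config = ReadingConfig.from_dict(config)
    level2, level1, link_models, cont, world = build_reading_model(config)
    rng = np.random.default_rng(seed)
    rec = ReadingRecord(config=config, world=world)

    n_s = len(world.sentences)
    D_link = word_link_matrix(world)
    true_sentence = world.true_sentence
    vf, hf = world.true_flips
    T1, iters = config.T1, config.iterations

    # level-2 belief state (single policy)
    nu2 = [np.zeros((4, n_s)), np.zeros((4, 4))]
    s2 = [softmax(v, axis=1) for v in nu2]
    obs2: list = [None] * 4
    extra2: list = [None] * 4
    log_D2 = _log_priors(level2, None)

    gaze = np.zeros(2)            # persistent true gaze
    mu_gaze = np.zeros(2)         # persistent believed gaze
    sent_raster, word_raster = [], []
    sent_hold = s2[0][0].copy()   # sentence belief held while level 1 runs
    bin_count = 0

    for t2 in range(4):
        # ----- descending message: empirical prior over the word ---------
        joint = np.multiply.outer(s2[0][t2], s2[1][t2]).reshape(-1)
        word_prior = descending_message(D_link, joint)
        true_word = world.sentences[true_sentence][t2]
        layout = world.word_layouts[(true_word, vf, hf)]

        # ----- level-1 trial over this word ------------------------------
        d_flip = np.array([config.flip_prior, 1.0 - config.flip_prior])
        D1 = [word_prior, np.full(4, 0.25), d_flip, d_flip.copy()]
        log_D1 = _log_priors(level1, D1)
        nP = level1.n_policies
        nu1 = [[np.zeros((T1, n)) for n in level1.state_dims] for _ in range(nP)]
        s1 = [[softmax(v, axis=1) for v in nu1[p]] for p in range(nP)]
        pi1 = np.full(nP, 1.0 / nP)
        obs1: list = [None] * T1
        word_rec = {"soft_obs": [], "pi": [], "G": [], "actions": []}

        for t1 in range(T1):
            pots = _obs_logpots(level1, obs1)
            for _ in range(iters):
                for p in range(nP):
                    gradient_iteration(level1, s1[p], nu1[p], pots, p,
                                       log_D1, step=config.step)
                bma_now = bayesian_model_average(s1, pi1)
                word_raster.append(bma_now[0][0])
                sent_raster.append(sent_hold)
                bin_count += 1
            G1 = np.array([expected_free_energy(level1, s1[p], from_epoch=t1 + 1)
                           for p in range(nP)])
            # the marginal-F term suppresses policies whose past actions are
            # inconsistent with the outcomes observed so far
            F1 = np.array([marginal_free_energy(level1, s1[p], pots, p, log_D1)
                           for p in range(nP)])
            pi1 = policy_posterior(G1, config.gamma, F=F1 - F1.min())
            word_rec["pi"].append(pi1.copy())
            word_rec["G"].append(G1)

            if t1 == T1 - 1:
                break
            # ----- act: choose the next quadrant and saccade to it -------
            (q_cmd,) = select_action(pi1, level1.policies, t1)
            word_rec["actions"].append(q_cmd)
            what_pred = _predict_what(level1, s1, pi1, t1 + 1, q_cmd)
            prior_o = np.kron(what_pred, onehot(q_cmd, 4))
            link = LinkSpec(models=link_models, prior_o=prior_o)

            target = world.quadrant_centers[q_cmd]
            true_glyph = layout[q_cmd]
            vis_true = lambda x: sample_visual(world, true_glyph, x, target).ravel()
            do_da = np.zeros((2, 1026, 2))
            do_da[0, 1024:, :] = config.action_gain * np.eye(2)
            do_da[1, 1024:, :] = config.action_gain * np.eye(2)
            proc = ContinuousProcess(
                f=lambda x, a: a,
                g=lambda x: np.concatenate([vis_true(x), x]),
                g1=lambda x, a: np.concatenate([np.zeros(1024), a]),
                x0=gaze.copy(), dim_a=2,
                noise_x_std=np.sqrt(config.process_noise_var),
                noise_o_std=np.concatenate([
                    np.full(1024, np.sqrt(config.obs_noise_var)), np.zeros(2)]),
                _do_da=do_da)
            st = GeneralizedState.zeros(cont, dim_a=2)
            st.mu_x[0] = mu_gaze.copy()
            post_o, traj = link_cycle(
                link, cont, proc, config.n_steps_per_saccade, config.dt,
                rng=rng, state=st, method="local_linear")
            gaze = traj.x_true[-1].copy()
            mu_gaze = traj.mu_x[-1, 0].copy()
            rec.saccade_onset_bins.append(bin_count)

            # accumulated-evidence weights (prior removed) become the soft
            # discrete outcomes for the word level
            w = softmax(link.L)
            what_soft = normalize(w.reshape(4, 4).sum(axis=1))
            where_soft = normalize(w.reshape(4, 4).sum(axis=0))
            obs1[t1 + 1] = (what_soft, where_soft)
            word_rec["soft_obs"].append((what_soft, where_soft))
            rec.saccades.append(SaccadeRecord(
                word_index=t2, epoch=t1 + 1, target_quadrant=q_cmd,
                true_glyph=true_glyph, gaze=traj.x_true.copy(),
                mu_gaze=traj.mu_x[:, 0].copy(), action=traj.a.copy(),
                posterior_o=post_o.copy(), what_weights=what_soft.copy(),
                F=traj.F.copy()))

        bma1 = bayesian_model_average(s1, pi1)
        rec.word_bma.append(bma1[0][0].copy())
        rec.words_read.append(word_rec)

        # ----- ascending message to the sentence level -------------------
        # evidence applies to the position actually read (observed), so the
        # other position columns stay neutral
        ratio = bma1[0][0] / np.maximum(word_prior, LOG_FLOOR)
        ev = ascending_message(D_link, ratio).reshape(n_s, 4)
        extra = np.zeros((n_s, 4))
        extra[:, t2] = ev[:, t2]
        extra2[t2] = extra
        obs2[t2] = (t2,)          # proprioceptive position signal

        pots2 = _obs_logpots(level2, obs2)
        pots2 = [a if b is None else (b if a is None else a + b)
                 for a, b in zip(pots2, extra2)]
        for _ in range(iters):
            gradient_iteration(level2, s2, nu2, pots2, 0, log_D2,
                               step=config.step)
            sent_raster.append(s2[0][0].copy())
            word_raster.append(bma1[0][0])
            bin_count += 1

        sentence_posterior = s2[0][0].copy()   # initial-state (sentence) belief
        sent_hold = sentence_posterior
        rec.sentence_bma.append(sentence_posterior)
        rec.sentence_entropy.append(entropy(sentence_posterior))

    rec.level2_raster = np.array(sent_raster).T
    rec.level1_raster = np.array(word_raster).T
    rec.ephys = simulate_ephys(rec, bin_dt=config.bin_dt, band=config.band)
    return rec


# ---------------------------------------------------------------------------
# simulated electrophysiology
# ---------------------------------------------------------------------------

def band_power_fraction(trace: np.ndarray, fs: float, band) -> float:
    """Fraction of spectral power inside ``band`` (Welch periodogram)."""
    f, P = signal.welch(trace, fs=fs, nperseg=min(len(trace), 1024))
    total = P[f > 0.5].sum()
    if total <= 0:
        return 0.0
    inside = P[(f >= band[0]) & (f <= band[1])].sum()
    return float(inside / total)


def simulate_ephys(record: ReadingRecord, bin_dt: float = 0.016,
                   band=(4.0, 32.0), fs: float = 1000.0) -> EphysRecord:
    """Turn Bayesian-model-average traces into rasters and simulated LFPs.

    Rasters are the per-iteration expectations of the sentence units (level
    2) and word units (level 1).  Depolarization traces are obtained by
    linear interpolation onto an ``fs`` grid followed by a 4th-order
    zero-phase Butterworth band-pass — the default 4–32 Hz captures the
    saccade-locked transients.
    """
    rasters = {"sentence": np.asarray(record.level2_raster, dtype=float),
               "word": np.asarray(record.level1_raster, dtype=float)}
    n_bins = rasters["sentence"].shape[1]
    bin_times = (np.arange(n_bins) + 0.5) * bin_dt
    duration = n_bins * bin_dt
    min_len = int(3 * fs / band[0])
    times = np.arange(0, duration, 1.0 / fs)
    if times.size < min_len:
        warnings.warn("record shorter than filter warm-up; padding")
        times = np.arange(0, min_len / fs, 1.0 / fs)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    lfp = {}
    for name, r in rasters.items():
        up = np.stack([np.interp(times, bin_times, row, left=row[0],
                                 right=row[-1]) for row in r])
        lfp[name] = signal.sosfiltfilt(sos, up, axis=1)
    onsets = np.array(record.saccade_onset_bins, dtype=float) * bin_dt
    return EphysRecord(rasters=rasters, lfp=lfp, fs=fs, bin_dt=bin_dt,
                       band=tuple(band), times=times, bin_times=bin_times,
                       saccade_onsets=onsets)
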