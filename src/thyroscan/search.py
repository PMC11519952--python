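"""Panoramic sliding-window search environment and a reference DQN.

The probe-search problem is abstracted as a 1-D sliding window over a
stitched panorama of the neck: the agent sees the (optionally
shadow-augmented) crop under the window and must move LEFT/RIGHT by one
stride or STAY.  An episode succeeds when the agent STAYs with the window
within the goal tolerance.  Optional goal drift emulates patient motion
between steps.

The published system trains a deep Q-network on real panoramas; its reward,
action granularity and termination rule are not stated, so the defaults
here (+10 terminal STAY bonus, -0.1 per step, distance-difference shaping)
are configuration, not claims about the original.  The Q-network is a small
fully connected net implemented directly in numpy (forward, backward and
Adam), which is ample at this observation size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import Panorama, USFrame, VirtualProbe, apply_shadow_mask, downsample

_OBS_PROBE = VirtualProbe()

LEFT, RIGHT, STAY = 0, 1, 2
ACTIONS = (LEFT, RIGHT, STAY)


@dataclass
class RewardConfig:
    """Shaped reward: terminal STAY bonus, step cost and approach shaping."""

    success: float = 10.0
    step_cost: float = -0.1
    shaping: bool = True


@dataclass
class EpisodeResult:
    total_reward: float
    length: int
    success: bool
    trajectory: list[int] = field(default_factory=list)


class PanoramaEnv:
    """Episodic reset/step environment over a panorama.

    Observations are window crops downsampled to ``obs_shape`` and scaled to
    [0, 1].  The window position is clipped to the panorama bounds.
    """

    def __init__(
        self,
        panorama: Panorama | np.ndarray,
        window_width: int | None = None,
        stride: int = 20,
        goal_position: int | None = None,
        goal_tolerance: int = 10,
        max_steps: int = 50,
        shadow_severity: float = 0.0,
        drift_step: int = 0,
        obs_shape: tuple[int, int] = (16, 16),
    ):
        if isinstance(panorama, Panorama):
            self.image = panorama.image
            window_width = window_width or panorama.window_width_px
            goal_position = (
                panorama.goal_position_px if goal_position is None else goal_position
            )
        else:
            self.image = np.asarray(panorama)
            if window_width is None or goal_position is None:
                raise ValueError("raw-array env needs window_width and goal_position")
        if stride <= 0:
            raise ValueError("stride must be positive")
        if goal_tolerance < 0:
            raise ValueError("goal tolerance must be >= 0")
        if window_width > self.image.shape[1]:
            raise ValueError("window wider than the panorama")
        self.window_width = int(window_width)
        self.stride = int(stride)
        self.goal = int(np.clip(goal_position, 0, self.max_position))
        self.goal_tolerance = int(goal_tolerance)
        self.max_steps = int(max_steps)
        self.shadow_severity = float(shadow_severity)
        self.drift_step = int(drift_step)
        self.obs_shape = obs_shape
        self._rng = np.random.default_rng(0)
        self._pos: int | None = None
        self._steps = 0
        self._done = True

    @property
    def max_position(self) -> int:
        return self.image.shape[1] - self.window_width

    @property
    def position(self) -> int:
        if self._pos is None:
            raise RuntimeError("environment not reset")
        return self._pos

    def _observe(self) -> np.ndarray:
        crop = self.image[:, self._pos : self._pos + self.window_width]
        if self.shadow_severity > 0:
            frame = USFrame(
                crop.astype(np.uint8),
                1.0,
                np.zeros_like(crop, dtype=bool),
                {},
                _OBS_PROBE,
                0,
            )
            crop = apply_shadow_mask(
                frame, self.shadow_severity, seed=int(self._rng.integers(2**31))
            ).image
        if self.obs_shape is None:
            return crop.astype(np.float64) / 255.0
        return downsample(crop, self.obs_shape) / 255.0

    def reset(self, seed: int | None = None) -> np.ndarray:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self._pos = int(self._rng.integers(0, self.max_position + 1))
        self._steps = 0
        self._done = False
        return self._observe()

    def step(self, action: int, reward_config: RewardConfig | None = None):
        """Apply one action; returns (observation, reward, done, info)."""
        if self._done:
            raise RuntimeError("step called on a finished episode; reset first")
        if action not in ACTIONS:
            raise ValueError(f"invalid action {action}")
        rc = reward_config or RewardConfig()
        prev_dist = abs(self._pos - self.goal)
        if action == LEFT:
            self._pos = max(0, self._pos - self.stride)
        elif action == RIGHT:
            self._pos = min(self.max_position, self._pos + self.stride)
        self._steps += 1

        success = action == STAY and abs(self._pos - self.goal) <= self.goal_tolerance
        reward = rc.step_cost
        if rc.shaping:
            reward += (prev_dist - abs(self._pos - self.goal)) / self.stride
        if success:
            reward += rc.success
        done = success or self._steps >= self.max_steps
        self._done = done

        if not done and self.drift_step:
            self.goal = int(
                np.clip(
                    self.goal + self._rng.integers(-self.drift_step, self.drift_step + 1),
                    0,
                    self.max_position,
                )
            )
        info = {"position": self._pos, "goal": self.goal, "success": success}
        return self._observe(), float(reward), done, info


def greedy_distance_policy(env: PanoramaEnv):
    """Oracle policy that knows the goal: move toward it, then STAY."""

    def policy(obs, info=None):
        pos = info["position"] if info else env.position
        if abs(pos - env.goal) <= env.goal_tolerance:
            return STAY
        return LEFT if pos > env.goal else RIGHT

    return policy


def tabular_optimal_actions(env: PanoramaEnv, reward_config: RewardConfig | None = None,
                            gamma: float = 0.95) -> dict[int, int]:
    """Value iteration on the position abstraction of the env (drift off).

    States are the reachable window positions; used as an independent check
    of what a trained policy should do.
    """
    rc = reward_config or RewardConfig()
    positions = sorted(
        {int(np.clip(p, 0, env.max_position)) for p in range(0, env.max_position + 1)}
    )
    v = {p: 0.0 for p in positions}
    moves = {
        LEFT: lambda p: max(0, p - env.stride),
        RIGHT: lambda p: min(env.max_position, p + env.stride),
        STAY: lambda p: p,
    }

    def r_and_next(p, a):
        q = moves[a](p)
        success = a == STAY and abs(q - env.goal) <= env.goal_tolerance
        r = rc.step_cost
        if rc.shaping:
            r += (abs(p - env.goal) - abs(q - env.goal)) / env.stride
        if success:
            r += rc.success
        return r, q, success

    for _ in range(500):
        delta = 0.0
        for p in positions:
            best = -np.inf
            for a in ACTIONS:
                r, q, done = r_and_next(p, a)
                best = max(best, r + (0.0 if done else gamma * v[q]))
            delta = max(delta, abs(best - v[p]))
            v[p] = best
        if delta < 1e-9:
            break
    out = {}
    for p in positions:
        qs = []
        for a in ACTIONS:
            r, q, done = r_and_next(p, a)
            qs.append(r + (0.0 if done else gamma * v[q]))
        out[p] = int(np.argmax(qs))
    return out


# ---------------------------------------------------------------------------
# numpy MLP and DQN
# ---------------------------------------------------------------------------


class MLP:
    """Two-layer ReLU MLP with Adam, sufficient for a Q-function at this scale."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        lim1 = np.sqrt(6.0 / (n_in + n_hidden))
        lim2 = np.sqrt(6.0 / (n_hidden + n_out))
        self.params = [
            rng.uniform(-lim1, lim1, (n_in, n_hidden)),
            np.zeros(n_hidden),
            rng.uniform(-lim2, lim2, (n_hidden, n_out)),
            np.zeros(n_out),
        ]
        self._m = [np.zeros_like(p) for p in self.params]
        self._v = [np.zeros_like(p) for p in self.params]
        self._t = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        w1, b1, w2, b2 = self.params
        return np.maximum(x @ w1 + b1, 0.0) @ w2 + b2

    def train_step(self, x, actions, targets, lr=1e-3):
        """One Adam step on the MSE of Q(s, a) against the TD targets."""
        w1, b1, w2, b2 = self.params
        z1 = x @ w1 + b1
        h = np.maximum(z1, 0.0)
        q = h @ w2 + b2
        n = x.shape[0]
        dq = np.zeros_like(q)
        dq[np.arange(n), actions] = 2.0 * (q[np.arange(n), actions] - targets) / n
        dw2 = h.T @ dq
        db2 = dq.sum(axis=0)
        dh = dq @ w2.T
        dz1 = dh * (z1 > 0)
        dw1 = x.T @ dz1
        db1 = dz1.sum(axis=0)
        grads = [dw1, db1, dw2, db2]
        self._t += 1
        b1c, b2c = 1 - 0.9**self._t, 1 - 0.999**self._t
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            m *= 0.9
            m += 0.1 * g
            v *= 0.999
            v += 0.001 * g**2
            p -= lr * (m / b1c) / (np.sqrt(v / b2c) + 1e-8)
        loss = float(((q[np.arange(n), actions] - targets) ** 2).mean())
        return loss

    def copy_from(self, other: "MLP") -> None:
        for p, q in zip(self.params, other.params):
            p[...] = q


@dataclass
class DQNHyperparams:
    total_steps: int = 8000
    exploration_steps: int = 3000  # the original trains 30,000 exploration steps
    eps_start: float = 1.0
    eps_end: float = 0.05
    gamma: float = 0.95
    lr: float = 1e-3
    batch_size: int = 32
    buffer_size: int = 5000
    warmup: int = 200
    target_sync: int = 250
    hidden: int = 64
    eval_interval: int = 400

    def __post_init__(self) -> None:
        if self.total_steps <= 0 or self.exploration_steps <= 0:
            raise ValueError("step counts must be positive")
        if not 0 <= self.eps_end <= self.eps_start <= 1:
            raise ValueError("epsilon schedule must satisfy 0<=end<=start<=1")


@dataclass
class DQNPolicy:
    """Greedy policy over a trained Q-network."""

    net: MLP
    obs_shape: tuple[int, int]

    def __call__(self, obs: np.ndarray, info=None) -> int:
        q = self.net.forward(obs.ravel()[None, :])
        return int(np.argmax(q[0]))


def dqn_train(
    env: PanoramaEnv,
    hyperparams: DQNHyperparams | None = None,
    seed: int = 0,
    reward_config: RewardConfig | None = None,
):
    """Standard DQN: replay buffer, linear epsilon decay, target network.

    Returns ``(policy, curve)`` where the curve is a list of dicts with the
    mean episode reward and length per evaluation interval.
    """
    hp = hyperparams or DQNHyperparams()
    rng = np.random.default_rng(seed)
    n_in = int(np.prod(env.obs_shape))
    net = MLP(n_in, hp.hidden, len(ACTIONS), rng)
    target = MLP(n_in, hp.hidden, len(ACTIONS), rng)
    target.copy_from(net)

    buf_s = np.zeros((hp.buffer_size, n_in))
    buf_a = np.zeros(hp.buffer_size, dtype=np.int64)
    buf_r = np.zeros(hp.buffer_size)
    buf_s2 = np.zeros((hp.buffer_size, n_in))
    buf_d = np.zeros(hp.buffer_size)
    buf_n, buf_i = 0, 0

    curve = []
    interval_rewards: list[float] = []
    interval_lengths: list[int] = []
    obs = env.reset(seed=int(rng.integers(2**31))).ravel()
    ep_reward, ep_len = 0.0, 0

    for step in range(1, hp.total_steps + 1):
        frac = min(step / hp.exploration_steps, 1.0)
        eps = hp.eps_start + frac * (hp.eps_end - hp.eps_start)
        if rng.random() < eps:
            action = int(rng.integers(len(ACTIONS)))
        else:
            action = int(np.argmax(net.forward(obs[None, :])[0]))

        obs2, reward, done, info = env.step(action, reward_config)
        obs2 = obs2.ravel()
        ep_reward += reward
        ep_len += 1

        buf_s[buf_i], buf_a[buf_i], buf_r[buf_i] = obs, action, reward
        buf_s2[buf_i], buf_d[buf_i] = obs2, float(done)
        buf_i = (buf_i + 1) % hp.buffer_size
        buf_n = min(buf_n + 1, hp.buffer_size)

        if done:
            interval_rewards.append(ep_reward)
            interval_lengths.append(ep_len)
            ep_reward, ep_len = 0.0, 0
            obs = env.reset(seed=int(rng.integers(2**31))).ravel()
        else:
            obs = obs2

        if buf_n >= hp.warmup:
            pick = rng.integers(0, buf_n, hp.batch_size)
            q_next = target.forward(buf_s2[pick]).max(axis=1)
            targets = buf_r[pick] + hp.gamma * (1.0 - buf_d[pick]) * q_next
            net.train_step(buf_s[pick], buf_a[pick], targets, lr=hp.lr)
        if step % hp.target_sync == 0:
            target.copy_from(net)
        if step % hp.eval_interval == 0:
            curve.append(
                {
                    "step": step,
                    "mean_reward": float(np.mean(interval_rewards)) if interval_rewards else np.nan,
                    "mean_length": float(np.mean(interval_lengths)) if interval_lengths else np.nan,
                    "epsilon": eps,
                }
            )
            interval_rewards, interval_lengths = [], []

    return DQNPolicy(net, env.obs_shape), curve


def policy_eval(
    policy,
    env: PanoramaEnv,
    n_episodes: int,
    seed: int = 0,
    reward_config: RewardConfig | None = None,
):
    """Seeded evaluation; returns (stats dict, per-episode results)."""
    if n_episodes <= 0:
        raise ValueError("n_episodes must be positive")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_episodes):
        obs = env.reset(seed=int(rng.integers(2**31)))
        total, steps, success = 0.0, 0, False
        traj = [env.position]
        done = False
        info = {"position": env.position, "goal": env.goal, "success": False}
        while not done:
            action = policy(obs, info)
            obs, reward, done, info = env.step(action, reward_config)
            total += reward
            steps += 1
            traj.append(info["position"])
            success = info["success"]
        results.append(EpisodeResult(total, steps, success, traj))
    stats = {
        "success_rate": float(np.mean([r.success for r in results])),
        "mean_reward": float(np.mean([r.total_reward for r in results])),
        "mean_length": float(np.mean([r.length for r in results])),
    }
    return stats, results


def random_policy(seed: int = 0):
    """Uniformly random action policy (evaluation baseline)."""
    rng = np.random.default_rng(seed)

    def policy(obs, info=None):
        return int(rng.integers(len(ACTIONS)))

    return policy
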