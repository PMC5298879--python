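# Methods

`axonmech` models the mechanics of *C. elegans* touch-receptor neuron (TRN)
axons — slender (~200 nm diameter) cylinders embedded in a crawling animal —
and implements the quantitative measurements used to characterize them:
shape tortuosity, bending-strain kinematics, FRAP diffusion, AFM contact
stiffness, microtubule-bundle morphometrics and spectrin periodicity. This
note records the models, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Elastic rod model

The axon is an extensible Kirchhoff rod characterized by a bending
stiffness `B`, twist rigidity `C` and axial stiffness `k`:

    B = E I,   C = 2 G I,   G = E / (2 (1 + nu)),   k_rod = E A / L,

with `I = pi r^4 / 4`, `A = pi r^2`, radius `r = 100 nm`. Measured bundle
stiffnesses can depart from the homogeneous-rod relations, so `B`, `C`
(through `G`) and `k` may also be set independently of `E`.

### Discretization

The centerline is a polyline; each edge carries a material frame obtained
by rotating a time-parallel reference frame through an angle `theta` about
the edge tangent. Bending energy is quadratic in the discrete curvature
binormal

    (kappa b)_j = 2 e_{j-1} x e_j / (|e_{j-1}||e_j| + e_{j-1}.e_j),

with Voronoi-length weighting; the junction material twist is
`phi_j = theta_j - theta_{j-1} + m_j`, where the reference twist `m_j` is
the holonomy of the parallel-transported frames, and twist energy is
`sum C phi_j^2 / (2 lbar_j)`. Stretch is Hookean per edge,
`(EA/2)(dl)^2/l0`; a constant-tension dead load on a sliding end is
available as an alternative ("tension" boundary mode). Self-contact is a
soft quadratic penalty (stiffness 200 pN/µm) activating when non-adjacent
segments approach within 1.1 diameters; this is what lets plectonemes form
without strand passage. Analytic gradients of all terms (including the
holonomy gradient of the reference twist, the curvature-binormal gradient
of bending, and the closest-point gradient of contact) are verified against
central differences to better than 1e-4 relative error in the test suite.

### Dynamics

Viscous forces dominate; vertices follow the overdamped gradient flow
`gamma dx/dt = -dH/dx` with per-vertex Stokes drag `gamma = 4 pi mu l`
(`mu = 1 Pa s`). Time stepping is semi-implicit: bending and stretch enter
through a banded SPD operator solved at the new positions (the bending
weight is raised locally where the rod is tightly curved, since the
straight-rod operator badly underestimates the bend Hessian inside a
winding loop), while twist coupling and contact stay explicit. The step
size is capped (0.5 s by default) so that drag-limited transport of
arclength along the rod — diffusivity ~ EA/gamma, a few µm²/s at the
reference mechanics — stays resolved; letting the implicit step grow
without bound silently equilibrates that transport and changes which
coiled states form. Every step is accepted only if the total energy
(including boundary work) does not increase; otherwise the step is halved.
Inside a tightening coil the landscape becomes a narrow corrugated valley
where strict per-step descent collapses the step size; there the
integrator switches to rollback bursts — a block of small fixed sub-steps
accepted only if the block's net energy decreased — so energy is
non-increasing at block granularity (the solver tolerance). With the
sharper segment-distance contact model (below) bursts are disabled and
the descent simply crawls through rough stretches.

Twist relaxes by damped Jacobi sweeps of the interior `theta` angles
(default one sweep per positional step, damping 0.05). This models slow,
adhesion-limited spinning of an axon embedded in tissue: torque transport
along the rod is then comparable to, not infinitely faster than, shape
relaxation, and several plectonemes can coexist instead of one coil
instantly draining the torque everywhere — which is what the quasi-static
alternative (`twist_mode="quasistatic"`, also provided) produces. A free
rod in water would spin much faster; the adhered-axon reading is the
default because TRN axons are mechanically coupled to the epidermis.
Junction reference twists are taken at their principal value; temporal
unwrapping was tried and rejected (near a fold the raw angle oscillates
across the branch cut and unwrapping ratchets phantom writhe into the
bookkeeping, silently shedding real twist).

Two self-contact models are provided: smooth vertex spheres (default;
radius inflated to cover the tube between vertices so strands cannot
thread the gaps — the effective numerical thickness is mesh-scale), and
exact segment-segment distances at the physical diameter (sharper
geometry; rough landscape, slower descent). The supercoiling reference
runs use the segment model, whose collapse trajectories reach genuine
multi-contact plectonemes.

### Supercoiling protocol

A straight rod clamped at both ends at its natural length cannot form
plectonemes under the quadratic (Hookean) axial law: every loop consumes
~2 pi r_loop of arclength, and the tension that builds after ~2% strain
arrests buckling in a shallow helix; this holds for every slack-supply
protocol we tried (instantaneous, time-ramped uniform, and end-fed slack
all coarsen to at most one coil). The printed rod energy's axial term is
linear in |l - l0|, i.e. constant tension: arclength then costs a fixed
force and coils can recruit length freely. The reference supercoiling run
therefore uses the constant-tension law at T = 2.5 pN — the upper end of
the measured axonal rest-tension scale (membrane tension ~2 µN/m times
the ~0.6 µm circumference gives ~1.3 pN, with cytoskeletal pre-stress on
top) — with the distributed twist set to 1.5x the buckling threshold
`tau_crit = 2 sqrt(T B)/C` of that tension, and a deterministic seeded
transverse perturbation (~1% of length) to break the symmetry of the
unstable straight state.

The symmetry-breaking perturbation is seeded coherently at the fastest-
growing helical mode of the twisted rod (wavelength
`2 pi 8B / [3M + sqrt(9M^2 - 32BT)]`, ~5.4 µm at the reference mechanics),
so every period of the instability develops together rather than a single
noise-leading site winning; 10% band-limited noise is superposed. Each
run is reported at a fixed horizon (the descent's own stopping point,
~9,000-10,000 s of model time): the rod winds into a solenoid that
collapses locally into compact self-contacting plectonemes. The
multi-plectoneme state is a long-lived transient, not a converged global
minimum — matching the dynamic, transient defects seen in moving animals.

Whether a particular rod exhibits one or several plectonemes at the
horizon is seed-dependent (nucleation is staggered; a coil's torque
relief suppresses nearby sites), and an inter-plectoneme spacing only
exists on rods with at least two. The spacing statistic is therefore
pooled over six seeded replicate rods — the same way interval statistics
are pooled over many neurons in vivo. Across replicates roughly half the
rods carry 2-5 plectonemes; individual multi-coil rods show mean
spacings from ~16 µm upward, and the pooled mean interval is ~20-25 µm,
slightly above the ~10-20 µm band of in-vivo defect intervals (staggered
nucleation occasionally skips a site, inflating individual intervals).

### Stability criteria and phase diagrams

The analytic buckling pair

    tau_crit = 2 sqrt(k B) / C,   k_crit = C^2 tau^2 / (4 B)

(with `k` a tension and `tau` a twist density) is implemented directly and
used for phase-diagram overlays. The coil/no-coil boundary comparison runs
in the constant-tension mode, where the criterion is exact; grids are
5x5 by default (log-spaced), desk scale, with per-cell failures flagged
rather than aborting the sweep.

### Coil detection

A plectoneme is a cluster of self-contacts: non-adjacent segment pairs
closer than 1.5 diameters (pairs nearer than 2 µm along the contour are
ignored — a smooth bend is not a contact), clustered along arclength with
a 2 µm merge gap. On reference shapes the counts are insensitive to ±20%
changes of the contact factor (tested). Spacing is the set of consecutive
centroid-to-centroid arclength distances.

## Shape deviation metric

For an ordered centerline, `<x^2>(n)` averages the squared displacement
between points `n` samples apart over all `N - n` windows (both coordinate
terms by default; a transverse-only switch exists because deviation is
conceptually perpendicular to the long axis). The fit
`<x^2> = S^2 n^2 + D n` over `n = 1..N/4` separates persistence `S` from
the deviation `D`; both coefficients are clipped at zero, since
unconstrained least squares can return numerically negative values for a
perfectly straight input (where `D = 0` and `<x^2> = n^2` exactly). `D` is
reported in the pixel convention; long windows are excluded because they
are noise-dominated and few.

Centerlines come from skeletonized binary images (longest endpoint-to-
endpoint geodesic through the skeleton graph; side branches drop out).
A 5-sample moving average removes the pixel staircase, which would
otherwise inflate arclength by ~5%. Body curvature is removed by
polynomial detrending of the transverse coordinate before defect analysis.
Defects are local maxima of the transverse coordinate above a threshold of
3x the median absolute deviation, capped at half the maximum excursion so
that dense regular undulations are also counted; spacings are arclength
gaps between defects.

Bending strain follows the Euler beam relation `eps = c z` (curvature
times distance from the neutral axis); neuron strain is `dL/L` with the
rest length taken at the frame of minimum mean absolute curvature
(configurable to first-frame).

## FRAP

One-dimensional diffusion gives a Gaussian bleach profile whose dispersion
obeys `w^2 = w0^2 + 2 D t`; `D` is half the slope of an ordinary
least-squares line through `w^2(t)` with free intercept (real bleach spots
have finite width at `t = 0`). Frames earlier than 0.5 s post-bleach are
excluded (fresh profiles are not yet Gaussian). Because an immobile pool
pins a single-Gaussian width fit near `w0`, each frame is decomposed into
a frozen component of fixed width `w0` plus a spreading mobile component;
the mobile width feeds the slope fit. The mobile fraction is the plateau
of the normalized ROI recovery `(I_t - I0)/(I_pre - I0)` fitted with
either the conventional exponential `f (1 - e^{-t/tau})` or the 1-D
diffusive shape `f (1 - (1 + t/tau)^{-1/2})`, keeping the better fit: the
exponential truncates the slow diffusive tail and biases `f` low when the
observation window is short. The ROI defaults to half the initial bleach
sigma, where the normalized recovery is closest to the ideal `1 - w0/w(t)`.

The generator models exactly this process (spreading mobile dip conserving
area, frozen immobile dip, additive Gaussian noise); recovery tests
therefore establish estimator correctness under the model's own
assumptions, not robustness to reaction-binding kinetics or 2-D geometry.

## AFM contact

The tip-axon contact is a Hertzian sphere-on-cylinder impact,
`F = a d^1.5`, fitted for `a` over 0-100 nm indentation (closed-form
projection; unweighted). The apparent modulus with a finite-stiffness
cantilever correction is

    E_axon = 9 a E_b K1^1.5 / (8 pi E_b sqrt(d K2) - 9 a K1^1.5),

with `E_b = 3.5 GPa` (Si), elliptic-integral constants `K1 = 1.71`,
`K2 = 0.89`, tip diameter `d = 60 nm`. The grouping is pinned by two
checks that do not depend on the algebra: the rigid-tip limit agrees to
~0.1% with an independently computed sphere-on-cylinder Hertz prefactor
(effective-radius theory with nu = 1/2), and `E(a)` is monotone on the
physical branch. The contact point of raw curves is placed where force
first exceeds 3 baseline standard deviations. Passing kPa where Pa is
expected trips a loud unit guard (axon moduli below 50 Pa are not
physical).

## Bundle morphometrics

Adjacency between MT profiles is Delaunay triangulation with edges longer
than 2.5x the median removed (deterministic, matches visual
nearest-neighbor intent). Edge-to-edge distances are center distance minus
both radii (12.5 nm default), floored at zero; touching pairs are excluded
from the geometric mean (log undefined) and reported as a contact
fraction. The spread is the raw-scale variance in nm². Bimodality (mixed
phenotypes) is flagged by a 2- vs 1-component Gaussian-mixture BIC
comparison on log-distances with a separation requirement. Inter-MT angles
are taken at each profile between all pairs of its adjacent neighbors.
Average MT length uses `L = 2 N a / T` (mean count per section, series
length, terminations).

PIV matches 32 px interrogation windows within 96 px search windows by
normalized cross-correlation (3-point parabolic sub-pixel refinement),
masking windows below 0.6 peak correlation or without texture (below 5% of
image-wide standard deviation — featureless background would correlate
spuriously). Each vector is anchored at its window's intensity centroid,
which removes a systematic underestimate of rotation when content sits off
the window center. The pitch profile bins displacement magnitudes radially
(median per annulus, robust to windows locking onto a lattice vector) and
converts via `theta(r) = atan(|d|(r)/z)` with `z = 100 nm` between
analyzed section pairs (50 nm sections, stride 2). The rigid rotation
between a section pair is estimated as the median per-window angle
`atan2(r x (r+d), r.(r+d))`; the rotation sense is the sign of the mean
tangential component, whose reversal along a stack marks a helical
perversion. A perfect unjittered lattice is degenerate for PIV (the
pattern matches itself one lattice vector over), so twisted-bundle tests
use realistic nm-scale jitter.

## Spectrin periodicity

Profiles are detrended by subtracting a 1 µm running mean, then scored by
a one-sided periodogram normalized so total power equals variance. The
dominant peak within the 100-400 nm period window is refined by a
Lorentzian fit with additive baseline; significance is the peak-to-median
ratio on a 5-bin-smoothed spectrum (smoothing tames the exponential tail
of single-bin periodogram noise), with threshold 4, calibrated on white-
noise nulls to a false-positive rate below 5%. Profiles without a
significant peak return an explicit null estimate.

## Synthetic data

Every generator is a pure function of parameters and a seed, and its
ground-truth record carries exactly the parameters the paired stage
estimates. Noise is additive Gaussian on intensities/forces and isotropic
Gaussian jitter on coordinates — matching the least-squares assumptions of
the fitters. The generators emulate the statistical structure each stage
assumes (Gaussian bleach dips, power-law force curves, jittered hexagonal
lattices rotated rigidly, cosine intensity lattices under Gaussian PSF,
arc-shaped worm bodies with offset parallel neurons, straight backbones
with inserted self-crossing loops). They do not emulate photon statistics,
camera artifacts, EM texture, segmentation errors or drift; passing
recovery tests demonstrates estimator correctness under these idealized
conditions, not performance on raw microscopy.

## Problem sizes

Default study sizes keep a full run at desk scale: supercoiling rods use
180-220 vertices over 70-75 µm (refinement tests show <1% energy change
on doubling), phase grids are 5x5, FRAP recovery grids use 60-frame
kymographs, and PIV stacks use 256 px sections. All randomness flows from
explicit integer seeds; repeated runs are bit-identical.

## Known limitations

- No inertial dynamics, anisotropic cross-sections, or coupling to a
  deforming body-wall model; the rod relaxes between static boundary
  conditions.
- The descent integrator finds local minima along a physically-motivated
  path; metastable multi-plectoneme states are the object of study, not a
  converged global optimum.
- Twist-transport speed (the Jacobi damping) is a modeling parameter with
  a qualitative justification (adhesion-limited spinning), not a measured
  quantity; the quasi-static limit is exposed for comparison.
- FRAP and AFM estimators assume the generative models above; binding
  kinetics, anomalous diffusion, substrate effects and cantilever
  calibration are out of scope.
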