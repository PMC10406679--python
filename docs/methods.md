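# Methods

This note records the geometric model behind `remorph`, the choices
made where the design was genuinely open, and what the synthetic
fixtures do and do not establish about real data.

## Mesh model and morphometrics

A surface is an indexed triangle mesh: vertices in the length units of
the source morphology (typically µm for EM reconstructions) and faces
wound counter-clockwise seen from outside. Surface area is the sum of
half cross-product magnitudes. Enclosed volume uses the divergence
theorem — the sum of signed tetrahedra spanned from an arbitrary apex —
and is defined only for *watertight* surfaces: every undirected edge
shared by exactly two faces with opposite directed orientation.

Two deliberate choices:

- **Volume sign.** The absolute value of the signed sum is returned, so
  a globally flipped but consistently wound mesh (common in EM
  reconstruction exports) still yields the correct magnitude. A closed
  mesh with *mixed* winding is rejected with a distinct error, because
  no magnitude is trustworthy there.
- **Component ranking.** "Keep largest component" ranks by surface
  area, not face count — robust to non-uniform tessellation. Ties go to
  the component containing the lowest original face index, making the
  filter deterministic.

Degenerate (repeated-index or zero-area) faces are dropped during
cleanup with a logged count. The bounding box breaks longest-axis ties
x before y before z; the sampler depends on this determinism.

### Decimation

Tessellation reduction is Garland–Heckbert quadric edge collapse:
area-weighted plane quadrics per vertex, cheapest edge first, collapse
position from the combined quadric (midpoint/endpoint fallback when
singular). Collapses that violate the edge link condition or flip a
surviving face normal are rejected, so watertight inputs stay
watertight. The quality contract — surface area and volume drift below
2% at a target ratio of 0.25 on the smooth sphere fixture — is part of
the test suite. No parity with any particular editor's decimation
modifier is claimed.

## Plane sections and slicing

All cuts are axis-aligned planes. Crossing triangles are clipped
(Sutherland–Hodgman) against the half-space; intersection points are
cached per undirected mesh edge so both sides and the cap share
vertices exactly and non-cap area is conserved to float precision.
Vertices within 1e-9 of the axis extent of the plane are snapped onto
it and belong to both pieces' boundary; zero-area fragments are
dropped. When the plane passes exactly through a vertex ring, the
cross-section boundary consists of whole mesh edges; these contribute
cut segments directly (no crossing faces exist in that case).

**Caps.** Cut segments are chained into closed loops; loop nesting is
resolved by containment (even depth = material boundary, odd = hole),
holes are bridged into their outer loop, and the region is triangulated
by ear clipping. Collinear runs along the cut (triangle-fan chords) are
kept attached — an ear is blocked by any non-coincident point on its
boundary — so every boundary vertex appears in the cap and the cap's
directed edges pair exactly with the shell's; watertight inputs yield
two watertight outputs. Cap triangles are added to both pieces with
opposite orientation.

**Cumulative measure.** Slicing inverts the monotone cumulative measure
m(c): in SA mode the clipped original-surface area below c (caps never
counted); in V mode the capped volume below c, computed without
building caps by placing the divergence-theorem apex *on* the cutting
plane, where the cap's contribution vanishes identically.

**Error margin.** The per-segment tolerance ε is interpreted as the
*relative* deviation of each segment's measure from the equal share
M/N, making it scale-free. Each cut is found by bisection on
[c_{k−1}, c_max] until |m(c) − k·M/N| ≤ (ε/2)(M/N) (at most 200
iterations), which bounds every segment's relative deviation by ε.
Sequential cut-finding is globally convergent because m is monotone; no
joint optimisation or randomness is involved. A locally flat cumulative
measure (a gap along the axis) exhausts the iteration cap and raises an
error naming the cut. Whether the original interactive tool treats its
margin as absolute or relative is not published; the relative contract
is this package's definition.

In volume mode the report lists each segment's original-surface area
and cap area separately, since conventions differ on whether cut faces
count toward surface area.

## Contour stitching (cloud → mesh)

Transforming point clouds to meshes is restricted to cell segments
whose points form closed loops stacked along one axis — the structure a
nanoprocess inherits from serial sectioning. Grouping tolerance along
the axis is 1e-6 × the extent; each group is ordered by angle about its
centroid, which assumes the loop is star-shaped there. Ambiguous
orderings (two points within 1e-9 rad) raise an error naming the
station rather than silently mis-ordering.

Consecutive loops are joined by a triangle strip: the monotone lattice
path on the loop-correspondence grid minimising total spanned edge
length (dynamic programming), with the cyclic start anchored at the
upper loop's vertex nearest the lower loop's first vertex. Exhaustive
search over all cyclic offsets would cost O(n·m·min(n,m)) and changes
nothing for star-shaped contour rings, so the nearest-vertex anchor is
used; unequal point counts are absorbed by the path advancing whichever
loop keeps the spanned edges short. End loops are capped with centroid
fans; global orientation is flipped if the signed volume comes out
negative. The stitched surface is validated to be edge-manifold and
consistently oriented; full triangle–triangle self-intersection testing
is not performed (known limitation — a sufficiently pathological
contour stack could self-intersect while remaining manifold).

## Surface sampling (mesh → cloud)

With d = (longest-axis extent)/grid_resolution, sampling stations sit
at cell centres min + (i+½)d along *each* axis — the longest axis gets
exactly `grid_resolution` stations, and centre placement avoids
tangent sections at the bounding planes. "Grid resolution" is read as
the station (circumvent) count along the longest axis, with the in-ring
arc-length spacing also d, making the sampling isotropic; whether the
original tool counts points or rings along that axis is not published,
and no point-placement parity is claimed. Each station's cross-section
loops are resampled at arc-length interval d from a deterministic
(lexicographically smallest) start, so every emitted point is a convex
combination of points on one mesh triangle — the on-surface invariant
is exact by construction. Stations with index i ≡ 0 (mod keep) are
retained per axis; rings are generated along all three axes and
near-coincident points from different axes are *not* deduplicated
unless an explicit dedup radius is passed.

## Synthetic fixtures

The fixture generators stand in for astrocyte EM data: watertight
analytic shapes (box; polygonal cylinder, cone, UV sphere; a
varying-radius tube emulating a varicose nanoprocess, default profile
1 + 0.5·sin(2πz/10) over height 10 with 64 sides) and stacked
contour-ring clouds (default: 20 stations of 24 points with a Gaussian
radius bulge on a 0.3 µm neck). All are deterministic — identical
parameters give bit-identical vertices — and their *polygonal* closed
forms are the test oracles, eliminating tessellation slack from
equality assertions.

What they do not capture: real reconstructions have non-convex,
branching cross-sections, non-uniform tessellation, self-contacts and
acquisition noise. Passing tests establish the geometric contracts
(conservation, watertight closure, convergence laws), not robustness to
segmentation artefacts; the component filter and degenerate-face
cleanup are the only repair steps provided.

Problem sizes in the test suite are desk-scale by design: 64-side
fixtures (256–8k faces), 10⁵-sample Monte-Carlo volume checks, slicing
at margins 1e-3–1e-7. The Monte-Carlo ray-parity oracle and all
brute-force cross-checks live only in the tests, with fixed seeds; the
toolkit itself is deterministic end to end. Reports include elapsed
wall time, which is the one output field that varies between otherwise
identical runs; all geometry outputs are byte-identical.

## I/O conventions

DAT point clouds are plain comma-separated x,y,z lines, no header (the
serial-section convention); a delimiter option accepts
whitespace-separated variants; the decimal separator is always ".".
OBJ is written with 1-based indices and six decimals (sub-nanometre at
µm scale) and read with fan triangulation of >3-gons, OBJ-standard
negative-index resolution, and line-numbered parse errors. Every CLI
run writes its outputs and a `report.dat` (tool, applied parameters,
elapsed seconds, computed values) into a freshly created run folder;
the report layout is human-readable key: value lines.
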