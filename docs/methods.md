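# Methods

## Coordinate system

All datasets live on an absolute axis produced by concatenating chromosomes
in an explicit, user-imposed order (the order of appearance in the
chrom.sizes file; no natural sort is applied). Coordinates are 0-based and
half-open throughout, so an absolute position exactly on a chromosome
boundary belongs to the following chromosome. The order is part of a
dataset's identity: it is persisted inside every pyramid container and is
never inferred. Inputs in 1-based dialects must be converted before
ingestion; the shipped readers (bedGraph, BED, raw contact text) assume
0-based half-open, which is those formats' native convention.

## Zoom levels and the z_max convention

Zoom 0 is the coarsest level and `max_zoom` the finest (base resolution
r0). We define

    max_zoom = min { z : tile_bins * r0 * 2^z >= g }

i.e. the smallest number of doublings after which a single tile covers the
genome. A floor-of-log expression gives the same answer only when g is an
exact power-of-2 multiple of `tile_bins * r0`; with the ceiling, the
requirement that zoom 0 fit the whole genome into one tile holds for every
genome size, and a ~3.1 Gb genome at 1 kb still lands on the familiar
1 k … 16.384 M doubling sequence. Tile width at zoom z is
`tile_bins * r0 * 2^(max_zoom - z)`: it doubles with every zoom-out step,
equals `tile_bins * r0` at the finest level, and is >= g at zoom 0. Only
power-of-2 resolution ladders are built; arbitrary integer multiples of r0
have no unambiguous tiling rule and are out of scope.

## Matrix aggregation and the diagonal

Contact matrices are symmetric and stored as the upper triangle once,
mirrored on access (a stored off-diagonal entry represents both (i, j) and
(j, i); the diagonal is stored once). Binning a contact list counts each
same-bin contact once on the diagonal. Aggregation to the next-coarser
level block-sums the *stored* entries with indices halved — exactly the
coarsening applied by the ecosystem's multi-resolution contact formats. The
consequence worth spelling out: a coarse off-diagonal entry equals the sum
of the corresponding 2x2 block of the full matrix, while a near-diagonal
pair that folds onto the coarse diagonal contributes its count once, not
twice. This is the unique convention under which k-fold aggregation is
bit-identical to re-binning the original contact list at `r0 * 2^k` (an
invariant the test suite checks on random inputs) and under which total
contact count is conserved at every level. "Total mass" in this package
always means total contact count, i.e. the sum of stored entries.

## Signal aggregation and missing values

1D signal is rasterized once at r0 (bin value = coverage-weighted mean of
the overlapping bedGraph intervals; bins with no coverage are missing),
then aggregated by summing adjacent pairs. Each level keeps, per bin, the
sum of non-missing base values and a count of missing base slots out of
`values_per_bin = 2^k`. Displayed values are `sum / (values_per_bin -
nan_count)`, missing when the bin is entirely uncovered — so a constant
track stays exactly constant at every zoom regardless of the missing-data
pattern, and coarse averages are never diluted by gaps. An odd trailing bin
is paired with an absent partner treated as all-missing; with that padding
convention both the total sum and the total count of non-missing base
values are invariant across levels.

## Annotation downsampling

Qualitative records cannot be summed, so coarse levels discard instead: per
tile region at each zoom, the `capacity_per_tile` records of highest
importance among those intersecting the tile are retained, ties broken by
(start, label) for determinism. Importance is user-supplied, drawn from a
seeded RNG, or set to the record's length/area (so large features surface
first when zoomed out). Because a child tile's candidate set is a subset of
its parent's, a record retained in a tile is retained in every child tile
it intersects; a record spanning several parent tiles may still win in one
and lose in another, which is inherent to per-tile top-k and visible only
at tile seams.

## Tiles and edge padding

Dense tiles always have the full fixed shape (256 x 256 bins in 2D, 1024
values in 1D); cells past the genome end are NaN, never zero, so edge tiles
cannot bias averages or totals. 2D tile (x, y) addresses the block at bin
offset (x * 256, y * 256) of the full symmetric matrix, answered from the
mirrored upper-triangle storage. Annotation tiles return every retained
record whose extent intersects the tile. Stitching all tiles of a zoom
level reproduces that level bit-exactly inside the genome extent.

## Container and service

A pyramid is one HDF5 file: format name, schema version, kind, r0,
max_zoom, tile_bins and the assembly as root metadata, one group per zoom
level (signal: sums + nan_counts; matrix: COO triplets of the upper
triangle; annotations: the record table plus per-tile retained indices).
Reads verify version and level completeness and refuse to reinterpret
anything silently.

The service is a registry (a JSON index next to the stored pyramid files,
so restarts are reproducible) plus pure query functions: list tilesets,
tileset_info, and batched tile fetches in which unknown or malformed ids
produce per-item error entries without failing the batch. Dense payloads
travel as base64 little-endian float32 with NaN for missing. The HTTP layer
is a plain WSGI app (`GET /api/v1/tilesets`, `tileset_info?d=uid`,
`tiles?d=uid.z.x[.y]`, `d` repeatable) served with the standard library;
routes are artifact-defined since no canonical route set exists. Responses
are deterministic functions of (registry, request). Each tile request is
logged with uid, address and latency.

## Linked views

View domains are real-valued and unclamped (continuous panning may carry a
viewport past the genome edge; it renders as blank space). Lock semantics:
*both* copies the initiating view's domains; *zoom* sets members' widths to
the initiator's while preserving their own centers; *location* sets centers
while preserving widths — the overview/detail pattern. Locks reconcile
member domains at creation time (initiated from the first uid listed), so
the coherence invariant holds from the moment the link exists rather than
after the next navigation. Propagation is single-step: navigating A updates
A's lock partners but does not cascade through those partners' other locks,
which keeps navigation idempotent and order-independent within one event. A
view holds at most one lock per kind; a *both* lock occupies both the
location and zoom slots, and conflicting links are rejected when made.
Value-scale synchronization between tracks is modeled as a shared
min/max range object only — no rendering is involved. Viewport projection
maps the source domains linearly through the target domains into a pixel
box, clipped, degenerating to zero area when the domains are disjoint; x
and y are locked independently (no forced square aspect).

## Synthetic data

The generator produces the shapes this backend must handle, not realistic
Hi-C: no ligation noise, no balancing weights, no trans contacts. Contacts
are intra-chromosomal bin pairs (default 10 kb sampling bins) drawn with
weight `(d + 1)^-alpha`, alpha = 1 (the canonical contact-probability decay
slope), boosted by beta = 3 when both ends fall inside one declared
TAD-like block; the expected within-block fraction therefore has the closed
form `sum(w | same block) / sum(w)`, which the tests compare against
empirical samples at 3 sigma. Signal is a unit baseline plus Gaussian peaks
with geometric runs of missing coverage (2% start rate, mean length 5
bins); annotation importances are exponential (scale 10), giving the
heavy-ish tail needed to exercise top-k retention. The default "demo
genome" is 5 Mb over two chromosomes — large enough for a two-level 2D
pyramid and a four-level 1D pyramid with multi-tile zooms, small enough
that every test and the acceptance script run in seconds. Everything is a
pure function of (spec, seed), with independent RNG streams per file type.
Passing tests on these fixtures demonstrates the correctness of the
arithmetic (aggregation, addressing, conservation, downsampling), not
robustness to the pathologies of real sequencing data.

## Numerical and degenerate-input choices

Sums are float64 end to end; the wire format narrows to float32, and tests
that compare served against directly extracted payloads do so after the
same narrowing. Bin counts are `ceil(g / bin_size)`, so the last bin may be
partial; tile payloads past it are NaN. `compute_max_zoom` returns 0 when
the genome already fits one tile. Empty contact lists produce all-zero (not
missing) matrices — absence of observed contacts is a zero count, whereas
absence of signal coverage is missing data. bedGraph overlaps are rejected
at parse time because the overlapped value would be ambiguous.

## Known limitations

No matrix balancing, expected-model normalization, or TAD/loop calling; no
bigWig/cooler interchange (the container is this package's own HDF5
layout); no authentication or federation in the service; annotation
downsampling offers no cross-tile global consistency beyond the per-tile
guarantee above; the view model stops at geometry and serialization — it
draws nothing.
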