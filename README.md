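# genotiles

Server-side core of a multiscale genome interaction-map viewer: multi-resolution
tile pyramids for Hi-C contact matrices, quantitative 1D signal (ChIP-seq,
RNA-seq coverage), and importance-ranked annotations; the zoom/tile
arithmetic to address them; a small tile-request service; and a declarative
model of composable linked views with location/zoom synchronization and
viewport projections.

It is aimed at people building or studying genome browsers in the web-map
(slippy-tile) tradition: data is pre-aggregated into a stack of resolutions
so that any viewport, at any scale, can be answered by fetching a handful of
fixed-size tiles instead of the whole dataset.

## The model

Chromosomes are concatenated in a fixed, explicit order, giving every locus
an absolute coordinate on a genome of size *g*. A dataset at base (finest)
resolution *r₀* is stored at every zoom level *z* ∈ {0, …, z_max}, where the
bin size at zoom *z* is *r₀*·2^(z_max−z) and z_max is the smallest number of
doublings after which one tile spans the genome:

    z_max = min { z : b · r₀ · 2^z ≥ g }

with *b* the tile size in bins — 256 for 2D matrix tiles (a 256 × 256 slice
of the contact matrix), 1024 for 1D tiles. For a ~3.1 Gb human genome at
*r₀* = 1 kb this gives the doubling sequence 1 k, 2 k, 4 k, …, 16.384 Mb.
A tile at zoom *z* is *t_w* = *b*·*r₀*·2^(z_max−z) bp wide, and the tile
covering absolute position *l_g* has index *t_p* = ⌊*l_g* / *t_w*⌋.

Coarser levels are built by recursive aggregation: matrix bins merge by
2 × 2 block sums (conserving total contact count), signal bins merge by
summing values while a parallel array counts missing values per bin (so
coarse levels can display honest averages), and annotations — which cannot
be summed — are downsampled by keeping, per tile, only the records of
highest *importance* (user-supplied, random-with-seed, or annotation size).

Views over these tilesets can be linked by **location** (equal centers,
free widths — overview/detail), **zoom** (equal widths, free centers), or
**both** (identical domains), and one view's extent can be projected as a
rectangle into another. The whole composition serializes to canonical JSON.

## Worked example

```python
import numpy as np
from genotiles import (Assembly, TileId, TilesetRegistry,
                       build_matrix_pyramid, make_demo)
from genotiles.io import read_contacts
from genotiles.tiling import extract_tile, tile_width

paths = make_demo("demo", seed=1)          # deterministic 5 Mb toy genome
assembly = Assembly.from_chromsizes(paths["chromsizes"])
contacts = read_contacts(paths["contacts"], assembly)
pyramid = build_matrix_pyramid(contacts, assembly, base_resolution_bp=10_000)
for z in range(pyramid.max_zoom + 1):
    lv = pyramid.levels[z]
    print(f"zoom {z}: bin size {lv.bin_size_bp:>6} bp, {lv.n_bins:>3} bins, "
          f"tile width {tile_width(pyramid, z):>9} bp, "
          f"total contacts {lv.total_mass():.0f}")
tile = extract_tile(pyramid, TileId("demo", pyramid.max_zoom, 0, 0))
print("tile payload:", tile.payload.shape,
      "| contacts in tile:", int(np.nansum(tile.payload)))
```

prints

```
zoom 0: bin size  20000 bp, 250 bins, tile width   5120000 bp, total contacts 10000
zoom 1: bin size  10000 bp, 500 bins, tile width   2560000 bp, total contacts 10000
tile payload: (256, 256) | contacts in tile: 10044
```

The 5 Mb demo genome needs one doubling before a 256-bin tile spans it, so
the pyramid has two levels; all 10 000 simulated contacts are present at
both (aggregation conserves mass). The finest tile covers the first 256 of
500 bins — all of chromosome A — and its payload sums to the contacts with
both ends in that region (off-diagonal bin pairs appear mirrored across the
diagonal, hence slightly more than the raw pair count).

The same pyramid can be registered and served:

```sh
genotiles ingest demo/demo.contacts.txt --kind contacts \
    --chromsizes demo/demo.chrom.sizes --resolution 10000 \
    --data-dir data --uid demo-hic
genotiles tile demo-hic.1.0.0 --data-dir data   # print a tile payload
genotiles serve --data-dir data --port 8989     # HTTP tile server
```

after which `GET /api/v1/tiles?d=demo-hic.1.0.0` returns the identical
payload as base64-encoded float32, with NaN marking cells beyond the genome
edge.

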