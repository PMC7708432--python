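"""Reconstruct 3D cells from hand-traced 2D contours.

Contours on different slices belong to the same cell when each encloses the
other's projected centroid; related contours connect into groups, wrongly
merged groups are split by DBSCAN on their centroids, and each group is
rasterized as the convex hull of its contours.
"""
import numpy as np

from biofilm3d import AnnotationContour, GridSpec, group_annotation_contours

def circle(cy, cx, r, n=24):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack([cy + r * np.cos(ang), cx + r * np.sin(ang)], axis=1)

grid = GridSpec((8, 40, 40))
contours = [
    AnnotationContour("z", 3, circle(10, 10, 5), annotator="r1"),
    AnnotationContour("z", 4, circle(10, 10, 4), annotator="r1"),  # same cell
    AnnotationContour("z", 3, circle(28, 28, 5), annotator="r1"),  # another cell
]
inst = group_annotation_contours(contours, grid, clustering_radius=3.0)
sizes = [int((np.asarray(inst.labels) == l).sum()) for l in inst.label_ids()]
print(f"{len(contours)} contours grouped into {inst.n_objects} cells; "
      f"voxel volumes {sizes}")
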