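# Default 21-trait definition set over three body planes.
# Landmark indices are 0-based. Planes: body (21 landmarks),
# small_xsec (9 landmarks), large_xsec (16 landmarks).
# Eye diameter is read as the mean of the horizontal (2-3) and vertical
# (4-5) bony-orbit distances; override this file to change any reading.
traits:
  - {name: dorsal_fin,            plane: body,       kind: distance,      landmarks: [[12, 13]]}
  - {name: anal_fin,              plane: body,       kind: distance,      landmarks: [[16, 17]]}
  - {name: pectoral_fin,          plane: body,       kind: distance,      landmarks: [[10, 11]]}
  - {name: tail_fin,              plane: body,       kind: distance,      landmarks: [[19, 20]]}
  - {name: caudal_peduncle,       plane: body,       kind: distance,      landmarks: [[15, 18]]}
  - {name: vertebra_thickness_sml, plane: small_xsec, kind: distance,     landmarks: [[3, 4]]}
  - {name: vertebra_thickness_lrg, plane: large_xsec, kind: distance,     landmarks: [[6, 7]]}
  - {name: xsec_diameter_sml,     plane: small_xsec, kind: distance,      landmarks: [[5, 7]]}
  - {name: xsec_diameter_lrg,     plane: large_xsec, kind: distance,      landmarks: [[12, 8]]}
  - {name: aerobic_muscle_sml,    plane: small_xsec, kind: mean_distance, landmarks: [[7, 8], [5, 6]], bilateral: true}
  - {name: aerobic_muscle_lrg,    plane: large_xsec, kind: mean_distance, landmarks: [[8, 9], [12, 13]], bilateral: true}
  - {name: aerobic_muscle_vert_lrg, plane: large_xsec, kind: mean_distance, landmarks: [[14, 15], [10, 11]], bilateral: true}
  - {name: eye_diameter,          plane: body,       kind: mean_distance, landmarks: [[2, 3], [4, 5]]}
  - {name: snout_length,          plane: body,       kind: distance,      landmarks: [[1, 0]]}
  - {name: eye_vertical_position, plane: body,       kind: distance,      landmarks: [[0, 6]]}
  - {name: head_length,           plane: body,       kind: distance,      landmarks: [[1, 7]]}
  - {name: head_width,            plane: body,       kind: distance,      landmarks: [[8, 9]]}
  - {name: body_centroid_size,    plane: body,       kind: centroid_size, landmarks: null}
  - {name: head_centroid_size,    plane: body,       kind: centroid_size, landmarks: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]}
  - {name: centroid_size_sml,     plane: small_xsec, kind: centroid_size, landmarks: null}
  - {name: centroid_size_lrg,     plane: large_xsec, kind: centroid_size, landmarks: null}
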