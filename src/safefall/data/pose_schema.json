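{
  "title": "safefall pose-JSON dialect",
  "format": "safefall-pose",
  "version": 1,
  "description": "Tracked 2D skeleton sequences as emitted by a person-detection / segmentation / tracking / pose-estimation pipeline. Image coordinates: origin top-left, x right, y down, units pixels. Keypoints follow the 17-point COCO convention in the order: nose, left_eye, right_eye, left_ear, right_ear, left_shoulder, right_shoulder, left_elbow, right_elbow, left_wrist, right_wrist, left_hip, right_hip, left_knee, right_knee, left_ankle, right_ankle.",
  "top_level": {
    "format": "string, must equal 'safefall-pose'",
    "version": "integer schema version",
    "sequences": "array of identity records"
  },
  "identity_record": {
    "subject_id": "string, opaque subject identifier",
    "track_id": "integer tracker identity",
    "fps": "number > 0, frames per second",
    "frame_size": "[width, height] in pixels",
    "cohort": "one of 'pre', 'post', 'unknown'",
    "quality_label": "'safe', 'hazardous' or null",
    "meta": "free-form object (simulator ground truth lives here)",
    "frames": "array of frame records, frame_index strictly increasing"
  },
  "frame_record": {
    "frame_index": "integer >= 0",
    "bbox": "[x_min, y_min, width, height], width > 0, height > 0",
    "keypoints": "array of exactly 17 [x, y, confidence] triples; confidence in [0, 1]",
    "visible": "array of 17 booleans, true = keypoint usable",
    "imputed": "array of 17 booleans, true = coordinates filled by gap repair"
  }
}
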