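region,structure,alpha_beta,metric_kind,metric_parameter,objective,variation
THORAX,Lungs,3,MEAN,,22.00,26.00
THORAX,Lungs,3,DOSE_AT_ABS_VOLUME,1500,22.00,26.00
THORAX,Lung,3,VOLUME_AT_DOSE,20,40,
THORAX,Brachial Plexus,3,DOSE_AT_ABS_VOLUME,3.0,75.00,90.00
THORAX,Brachial Plexus,3,DOSE_AT_ABS_VOLUME,0.03,90.00,110.00
THORAX,Bronchial Tree,3,DOSE_AT_ABS_VOLUME,0.1,120.00,140.00
THORAX,Bronchial Tree,3,DOSE_AT_ABS_VOLUME,0.03,130.00,150.00
THORAX,Bronchial Tree,3,DOSE_AT_ABS_VOLUME,5,90.00,95.00
THORAX,Thoracic Wall,3,DOSE_AT_ABS_VOLUME,30,80.00,100.00
THORAX,Thoracic Wall,3,DOSE_AT_ABS_VOLUME,5,120.00,140.00
THORAX,Esophagus,3,DOSE_AT_ABS_VOLUME,0.03,100.00,120.00
THORAX,Esophagus,3,DOSE_AT_ABS_VOLUME,0.1,90.00,110.00
THORAX,Esophagus,3,DOSE_AT_ABS_VOLUME,1.00,80.00,90.00
THORAX,Esophagus,3,DOSE_AT_ABS_VOLUME,5.00,70.00,90.00
THORAX,Heart,3,DOSE_AT_ABS_VOLUME,15,60.00,80.00
THORAX,Heart,3,DOSE_AT_ABS_VOLUME,0.1,85.00,130.00
THORAX,Spinal Canal,2,DOSE_AT_ABS_VOLUME,0.1,,
THORAX,Great Vessels,3,DOSE_AT_ABS_VOLUME,0.03,120.00,open
ABDOMEN,Kidney,3,DOSE_AT_ABS_VOLUME,200,15.00,20.00
ABDOMEN,Kidney,3,DOSE_AT_REL_VOLUME,75,12.00,15.00
ABDOMEN,Stomach,3,DOSE_AT_ABS_VOLUME,0.1,60.00,80.00
ABDOMEN,Stomach,3,DOSE_AT_ABS_VOLUME,1,54.00,70.00
ABDOMEN,Duodenum,3,DOSE_AT_ABS_VOLUME,0.1,60.00,80.00
ABDOMEN,Duodenum,3,DOSE_AT_ABS_VOLUME,1,54.00,70.00
ABDOMEN,Bowel,3,DOSE_AT_ABS_VOLUME,0.1,60.00,80.00
ABDOMEN,Bowel,3,DOSE_AT_ABS_VOLUME,0.5,54.00,70.00
ABDOMEN,Liver-GTV,3,DOSE_AT_ABS_VOLUME,700,18.00,25.00
ABDOMEN,Liver-GTV,3,MEAN,,25.00,30.00
ABDOMEN,Spinal Nerve,2,DOSE_AT_ABS_VOLUME,0.1,70.00,90.00
ABDOMEN,Cauda Equina,3,DOSE_AT_ABS_VOLUME,0.1,67.00,85.00
ABDOMEN,Sacral Plexus,2,DOSE_AT_ABS_VOLUME,0.1,67.00,85.00
PELVIS,Bladder,3,DOSE_AT_ABS_VOLUME,0.5,105.00,120.00
PELVIS,Bladder,3,DOSE_AT_ABS_VOLUME,2,95.00,105.00
PELVIS,Rectum,3,DOSE_AT_ABS_VOLUME,0.5,105.00,110.00
PELVIS,Rectum,3,DOSE_AT_ABS_VOLUME,2,95.00,105.00
PELVIS,Spinal Nerve,2,DOSE_AT_ABS_VOLUME,0.03,90.00,110.00
PELVIS,Spinal Nerve,2,DOSE_AT_ABS_VOLUME,1,75.00,90.00
PELVIS,Ureter,3,,,none,
PELVIS,Urethra,3,,,none,
PELVIS,Femoral Head,3,,,none,
PELVIS,Penile Bulb,3,,,none,
HEAD_AND_NECK,Brainstem,2,DOSE_AT_ABS_VOLUME,0.1,68.00,80.00
HEAD_AND_NECK,Chiasm,2,DOSE_AT_ABS_VOLUME,0.03,68.00,80.00
HEAD_AND_NECK,Cochlea ipsilateral,3,MEAN,,45.00,60.00
HEAD_AND_NECK,Cochlea contralateral,3,MEAN,,45.00,60.00
HEAD_AND_NECK,Optic Nerve,2,DOSE_AT_ABS_VOLUME,0.03,68.00,80.00
HEAD_AND_NECK,Trachea,3,DOSE_AT_ABS_VOLUME,0.03,120.00,140.00
HEAD_AND_NECK,Trachea,3,DOSE_AT_ABS_VOLUME,0.1,110.00,120.00
HEAD_AND_NECK,Brain,3,DOSE_AT_ABS_VOLUME,0.1,110.00,120.00
HEAD_AND_NECK,Carotid Artery + 1 mm,3,DOSE_AT_ABS_VOLUME,0.03,100.00,135.00
HEAD_AND_NECK,Mandible,3,MEAN,,40.00,60.00
HEAD_AND_NECK,Mandible,3,DOSE_AT_ABS_VOLUME,0.1,70.00,130.00
BRAIN,Brainstem,2,DOSE_AT_ABS_VOLUME,0.1,80.00,100.00
BRAIN,Chiasm,2,DOSE_AT_ABS_VOLUME,0.03,68.00,80.00
BRAIN,Optic Nerve,2,DOSE_AT_ABS_VOLUME,0.03,68.00,80.00
BRAIN,Retina,3,DOSE_AT_ABS_VOLUME,0.03,70.00,80.00
BRAIN,Lens,3,,,none,
BRAIN,Brain - GTV,3,DOSE_AT_ABS_VOLUME,0.1,100.00,120.00
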