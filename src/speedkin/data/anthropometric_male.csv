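segment,proximal_kp,distal_kp,mass_frac,com_ratio
head,Nose,Neck,0.0694,0.5002
trunk,Neck,MidHip,0.4346,0.4486
upper_arm_r,RShoulder,RElbow,0.0271,0.5772
upper_arm_l,LShoulder,LElbow,0.0271,0.5772
forearm_r,RElbow,RWrist,0.0223,0.6751
forearm_l,LElbow,LWrist,0.0223,0.6751
upper_leg_r,RHip,RKnee,0.1416,0.4095
upper_leg_l,LHip,LKnee,0.1416,0.4095
lower_leg_r,RKnee,RAnkle,0.0433,0.4459
lower_leg_l,LKnee,LAnkle,0.0433,0.4459
foot_r,RAnkle,RBigToe,0.0137,0.4415
foot_l,LAnkle,LBigToe,0.0137,0.4415
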