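state,rhwdi,rhwdi_negative,rhwdi_rank,hwdi,hwdi_rank
Nevada,0.00,1,1,1.03,1
South Carolina,0.01,0,2,3.81,45
Ohio,0.06,1,3,2.95,24
North Carolina,0.06,0,4,3.75,41
New Hampshire,0.12,0,5,2.70,18
Maine,0.14,0,6,2.75,20
Indiana,0.18,1,7,3.77,42
Delaware,0.23,1,8,3.29,31
Kansas,0.24,0,9,4.02,46
Alabama,0.25,1,10,3.02,27
Utah,0.26,0,11,1.84,4
Colorado,0.27,1,12,2.28,10
Louisiana,0.33,1,13,3.59,37
Iowa,0.33,0,14,3.29,32
Oklahoma,0.33,0,15,3.45,34
Alaska,0.37,1,16,2.54,16
Florida,0.38,0,17,2.75,21
Arizona,0.42,1,18,2.11,9
Montana,0.43,1,19,2.10,7
District of Columbia,0.48,1,20,4.08,48
Minnesota,0.52,1,21,2.40,13
Idaho,0.56,1,22,2.77,22
New York,0.66,0,23,2.74,19
Tennessee,0.71,1,24,2.35,12
California,0.74,0,25,2.10,8
Georgia,0.74,1,26,3.77,43
New Mexico,0.77,1,27,1.67,2
Wyoming,0.77,1,28,3.07,28
Massachusetts,0.78,0,29,2.40,14
Washington,0.79,0,30,3.11,29
Virginia,0.88,0,31,3.66,38
North Dakota,0.91,0,32,2.45,15
Texas,0.92,0,33,3.77,44
New Jersey,0.94,0,34,2.03,6
Pennsylvania,0.97,0,35,3.46,35
Mississippi,1.08,1,36,4.35,49
Connecticut,1.09,1,37,2.31,11
Missouri,1.18,1,38,3.72,40
Illinois,1.20,1,39,4.03,47
Vermont,1.22,0,40,3.01,26
Nebraska,1.27,0,41,3.70,39
Hawaii,1.47,0,42,1.73,3
Wisconsin,1.49,0,43,3.00,25
Kentucky,1.62,0,44,2.88,23
Maryland,1.79,0,45,3.42,33
West Virginia,1.84,0,46,2.02,5
Oregon,1.95,0,47,3.51,36
Arkansas,2.08,1,48,3.26,30
Rhode Island,2.11,0,49,2.67,17
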