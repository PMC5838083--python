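tag_id,location,start_date,end_date,duration_days,max_distance_km,total_distance_km
2103020,San Nicolas,11/16/03,11/24/03,8,119.43,223.3
2103029,San Nicolas,11/14/03,11/20/03,6,80.24,80.24
2103030,San Nicolas,11/18/03,11/22/03,4,37.92,79.15
2103033,San Nicolas,12/16/03,12/26/03,10,102.39,144.4
2103035,San Nicolas,12/3/03,12/9/03,6,78.78,95.11
2103036,San Nicolas,11/14/03,11/16/03,2,8.08,8.08
2103037,San Nicolas,11/18/03,11/23/03,5,64.58,92.85
2104001,San Nicolas,11/20/04,11/28/04,8,57.24,77.36
2104003,San Nicolas,11/2/04,11/16/04,14,456.95,895.12
2104004,San Nicolas,11/3/04,11/12/04,9,135.78,178.93
2104005,San Nicolas,10/31/04,11/10/04,10,100.06,181.96
2104006,San Nicolas,2/23/05,3/8/05,13,84.37,112.27
2104007,San Nicolas,11/24/04,12/10/04,16,168.62,230.69
2104008,San Nicolas,11/13/04,11/22/04,9,208.75,432.93
2104010,San Nicolas,11/1/04,11/9/04,8,95.77,160.51
2104011,San Nicolas,11/9/04,11/18/04,9,49.08,65.22
2104012,San Nicolas,11/2/04,11/12/04,10,126.25,238.12
2105019,San Miguel,12/17/05,12/23/05,6,163.08,227.6
2105020,San Miguel,12/14/05,12/19/05,5,50.13,101.04
2105021,San Miguel,1/5/06,1/15/06,10,369.27,746.64
2105022,San Miguel,11/18/05,11/25/05,7,136.5,273.04
2105023,San Miguel,1/30/06,2/7/06,8,210.3,264.3
2105024,San Miguel,12/29/05,1/5/06,7,105,222.76
2105025,San Miguel,1/8/06,1/13/06,5,165.75,273.12
2105026,San Miguel,1/11/06,1/19/06,8,355.4,705.26
2105027,San Miguel,1/5/06,1/11/06,6,47.8,77.29
2105028,San Miguel,12/21/05,12/29/05,8,321.62,537.21
2105029,San Nicolas,12/6/05,12/11/05,5,40.75,125.31
2105030,San Nicolas,12/13/05,12/25/05,12,255.98,447.27
2105031,San Nicolas,12/26/05,1/3/06,8,194.02,394.32
2105032,San Nicolas,12/2/05,12/7/05,5,49.22,129.57
2105033,San Nicolas,12/5/05,12/10/05,5,13.05,75.43
2105034,San Nicolas,12/6/05,12/12/05,6,8.02,62.97
2105035,San Nicolas,11/17/05,11/23/05,6,57.54,115.6
2105036,San Nicolas,12/25/05,12/31/05,6,143.47,263.84
2105037,San Nicolas,12/3/05,12/9/05,6,78.43,164
2105038,San Nicolas,12/28/05,1/6/06,9,100.79,177.77
2105039,San Nicolas,12/5/05,12/9/05,4,57.93,67.09
2105040,San Nicolas,12/7/05,12/23/05,16,226.93,275.41
2106001,San Nicolas,11/11/06,11/20/06,9,255.41,493.04
2106002,San Nicolas,11/3/06,11/10/06,7,124.96,223.36
2106003,San Nicolas,11/22/06,12/10/06,18,340.42,582.47
2106004,San Nicolas,11/4/06,11/14/06,10,96.23,228.58
2106005,San Nicolas,11/7/06,11/19/06,12,158.29,352.43
2106006,San Nicolas,11/20/06,11/25/06,5,34.05,69.54
2106007,San Nicolas,11/21/06,11/28/06,7,127.12,253.85
2106008,San Nicolas,11/5/06,11/10/06,5,5.02,8.31
2106009,San Nicolas,12/12/06,12/21/06,9,117.92,231.82
2106010,San Nicolas,11/15/06,11/29/06,14,218.31,484.83
2106011,San Nicolas,11/8/06,11/14/06,6,65.82,65.82
2106012,San Miguel,12/17/06,12/24/06,7,133.73,238.52
2106014,San Miguel,12/15/06,12/22/06,7,195.4,349.16
2106015,San Miguel,11/27/06,12/11/06,14,387.18,796.15
2106016,San Miguel,11/11/06,11/19/06,8,92.87,179.56
2106018,San Miguel,12/3/06,12/8/06,5,67.09,178.68
2106020,San Miguel,11/21/06,11/27/06,6,80.47,176.58
2106021,San Miguel,11/14/06,11/19/06,5,137.39,251.58
2107009,San Nicolas,11/21/07,11/27/07,6,121.95,240.23
2107010,San Nicolas,12/22/07,1/4/08,13,108.12,213.83
2107011,San Nicolas,12/31/07,1/6/08,6,41.3,84.56
2107012,San Nicolas,1/4/08,1/15/08,11,502.15,876.47
2107013,San Nicolas,11/28/07,12/8/07,10,243.75,498.97
2107014,San Nicolas,1/12/08,1/18/08,6,158.89,299.49
2107015,San Nicolas,11/11/07,11/19/07,8,74.07,134.17
2107016,San Nicolas,12/28/07,1/9/08,12,456.12,838.08
2107017,San Nicolas,11/25/07,12/5/07,10,248.24,509.06
2108001,San Nicolas,12/12/08,12/18/08,6,94.72,151.28
2108002,San Nicolas,12/14/08,12/21/08,7,102.9,218.35
2108003,San Nicolas,11/18/08,11/30/08,12,415.27,765.57
2108005,San Nicolas,11/19/08,11/29/08,10,185.83,397.52
2108006,San Nicolas,11/18/08,11/26/08,8,123.1,249.3
2108010,San Nicolas,12/18/08,1/10/09,23,120.26,157.86
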